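"""Synthetic injury time-course generator with ground-truth labels.

Emulates the structure of a regeneration time-course microarray matrix: a few
thousand genes measured over an ordered grid of post-injury time points, in
which the member genes of a "dynamic" pathway share a coherent temporal
template on top of independent per-gene noise. Two templates mirror the
biology the analysis is meant to detect: an early transient response (e.g.
inflammatory signalling in the first hours) and a late sustained response
(e.g. a signalling pathway that stays up through remodelling). Ground-truth
phase labels per set make the generator usable for type-I calibration and
power benchmarks.

Model for gene g at time t:

    x[g, t] = baseline_g + scale_g * (effect_s * template_phase(s)[t] + eps)

with ``eps ~ N(0, noise_sd^2)`` i.i.d.; genes in no non-null set get a zero
template. ``baseline_g`` and ``scale_g`` are per-gene nuisance parameters that
the pipeline's z-scaling removes exactly, so detectability is governed by the
effect/noise ratio alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ContractError
from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

PHASES = ("early_transient", "late_sustained", "null")

#: The nine-point post-injury grid used throughout: hours then days.
DEFAULT_TIME_LABELS = ("2h", "6h", "24h", "48h", "4d", "7d", "14d", "21d", "35d")


@dataclass(frozen=True)
class SetSpec:
    """One synthetic gene set: name, size, temporal phase, effect size."""

    name: str
    size: int
    phase: str = "null"
    effect: float = 0.0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ContractError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.size < 1:
            raise ContractError("set size must be >= 1")
        if self.effect < 0:
            raise ContractError("effect must be >= 0")
        if self.phase == "null" and self.effect != 0.0:
            raise ContractError("null-phase sets must have effect 0")


def default_sets() -> tuple[SetSpec, ...]:
    """Benchmark default: one early, one late dynamic set plus 18 null sets."""
    dynamic = (
        SetSpec("early_response", 50, "early_transient", 3.0),
        SetSpec("late_response", 50, "late_sustained", 3.0),
    )
    nulls = tuple(SetSpec(f"null_{i:02d}", 50) for i in range(18))
    return dynamic + nulls


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated dataset; defaults give the benchmark world."""

    n_genes: int = 2000
    time_labels: tuple[str, ...] = DEFAULT_TIME_LABELS
    noise_sd: float = 1.0
    baseline_sd: float = 2.0
    scale_range: tuple[float, float] = (0.5, 2.0)
    sets: tuple[SetSpec, ...] = field(default_factory=default_sets)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "time_labels", tuple(self.time_labels))
        object.__setattr__(self, "sets", tuple(self.sets))
        if len(self.time_labels) < 2:
            raise ContractError("need at least two time points")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ContractError("scale_range must satisfy 0 < lo <= hi")
        if any(s.size > self.n_genes for s in self.sets):
            raise ContractError("a set is larger than the gene universe")


@dataclass(frozen=True)
class SyntheticDataset:
    """Matrix + gene sets + ground-truth phase label per set."""

    matrix: ExpressionMatrix
    sets: GeneSetCollection
    truth: dict[str, str]


def make_templates(time_labels) -> dict[str, np.ndarray]:
    """Unit-norm, mean-centred temporal templates per phase.

    ``early_transient`` is positive over the first third of the grid and
    non-positive afterwards; ``late_sustained`` is non-positive early and
    positive and flat from the midpoint on; ``null`` is the zero vector.
    """
    m = len(time_labels)
    if m < 2:
        raise ContractError("need at least two time points")
    early_raw = np.zeros(m)
    early_raw[: max(1, -(-m // 3))] = 1.0  # first ceil(M/3) points active
    late_raw = np.zeros(m)
    late_raw[m // 2 :] = 1.0  # active from the midpoint on

    def finish(raw):
        centred = raw - raw.mean()
        return centred / np.linalg.norm(centred)

    return {
        "early_transient": finish(early_raw),
        "late_sustained": finish(late_raw),
        "null": np.zeros(m),
    }


def _assign_members(config: SyntheticConfig, rng) -> dict[str, np.ndarray]:
    """Disjoint member blocks for non-null sets; null sets drawn from the rest."""
    non_null = [s for s in config.sets if s.phase != "null"]
    total = sum(s.size for s in non_null)
    if total > config.n_genes:
        raise ContractError(
            f"disjoint non-null sets need {total} genes, universe has {config.n_genes}"
        )
    perm = rng.permutation(config.n_genes)
    members: dict[str, np.ndarray] = {}
    offset = 0
    for s in non_null:
        members[s.name] = np.sort(perm[offset : offset + s.size])
        offset += s.size
    pool = np.sort(perm[offset:])
    for s in config.sets:
        if s.phase != "null":
            continue
        if s.size > pool.size:
            raise ContractError(
                f"null set {s.name!r} of size {s.size} exceeds the "
                f"{pool.size} genes outside non-null sets"
            )
        members[s.name] = np.sort(rng.choice(pool, size=s.size, replace=False))
    return members


def simulate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw one dataset from the generative model; reproducible from the seed.

    Member lists of non-null sets are disjoint so truth labels are
    unambiguous; null sets are drawn (possibly overlapping each other) from
    the genes outside all non-null sets.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, len(config.time_labels)
    templates = make_templates(config.time_labels)

    members = _assign_members(config, rng)
    signal = np.zeros((n, m))
    for s in config.sets:
        if s.phase == "null" or s.effect == 0.0:
            continue
        signal[members[s.name]] += s.effect * templates[s.phase]

    baseline = rng.normal(0.0, config.baseline_sd, size=n)
    scale = rng.uniform(*config.scale_range, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, m))
    values = baseline[:, None] + scale[:, None] * (signal + noise)

    width = len(str(n - 1))
    gene_ids = tuple(f"g{i:0{width}d}" for i in range(n))
    matrix = ExpressionMatrix(gene_ids, config.time_labels, values)
    gene_sets = GeneSetCollection(
        tuple(
            GeneSet(
                name=s.name,
                description=f"synthetic ({s.phase})",
                members=tuple(gene_ids[i] for i in members[s.name]),
            )
            for s in config.sets
        )
    )
    truth = {s.name: s.phase for s in config.sets}
    return SyntheticDataset(matrix=matrix, sets=gene_sets, truth=truth)


def simulate_null_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Same world with every set forced to the null phase (effect 0)."""
    config = config or SyntheticConfig()
    null_sets = tuple(
        replace(s, phase="null", effect=0.0) for s in config.sets
    )
    return simulate_dataset(replace(config, sets=null_sets))
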