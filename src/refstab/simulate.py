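"""Synthetic data with known ground truth.

Every pipeline stage can be exercised without external data:

* Cq tables drawn from an additive model on the Cq scale (equivalently
  multiplicative/lognormal on template quantities):

      Cq = baseline_gene + group_effect(gene, treatment)
           + loading(sample) + N(0, bio_sd_gene) + N(0, tech_sd)

  The loading effect is shared by all genes of a sample, which is what
  the ratio-based algorithms are built to cancel; treatment-dependent
  shifts make genes unstable in the NormFinder sense; per-gene biological
  noise makes them unstable in the geNorm/BestKeeper sense.
* RPKM-like expression matrices with lognormal baselines, planted
  ultra-stable genes, differentially expressed genes with treatment fold
  changes, and planted low-expression genes for the screening filter.
* Dilution series for standard-curve efficiency estimation.

All generators are deterministic given a seed and return the ground
truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CqTable, ExpressionTable, RefstabError
from .quantification import DilutionSeries


@dataclass(frozen=True)
class Design:
    """Full-factorial experimental design: treatments x timepoints x reps."""

    treatments: tuple[str, ...] = ("mock", "Pf", "DC3000", "dHopQ1-1")
    timepoints: tuple[str, ...] = ("6h", "12h")
    n_bio: int = 3
    n_tech: int = 3

    def annotations(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f"{t}_{tp}_r{r}",
                "group": t,
                "timepoint": tp,
                "bio_rep": r,
            }
            for t in self.treatments
            for tp in self.timepoints
            for r in range(1, self.n_bio + 1)
        ]
        return pd.DataFrame(rows)

    @property
    def n_samples(self) -> int:
        return len(self.treatments) * len(self.timepoints) * self.n_bio


#: The validation experiment's layout: 4 treatments x 2 timepoints x 3
#: biological x 3 technical replicates -> 24 samples, 72 wells per gene.
STUDY_DESIGN = Design()


@dataclass
class CqSimConfig:
    """Ground-truth parameters for :func:`simulate_cq_dataset`.

    ``noise_sd`` is the per-gene biological SD in cycles; ``group_effects``
    maps gene -> {treatment: shift in cycles}; ``baseline_cq`` (drawn
    uniformly in [15, 30] when not given) is the per-gene level;
    ``loading_sd`` generates a shared per-sample shift and ``tech_sd``
    the technical-replicate noise.  A gene is "stable" when it has no
    group effect and biological SD at most ``stable_threshold``.
    """

    genes: tuple[str, ...]
    noise_sd: dict[str, float]
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_cq: dict[str, float] | None = None
    loading_sd: float = 0.3
    tech_sd: float = 0.1
    stable_threshold: float = 0.2

    def __post_init__(self):
        for g in self.genes:
            if g not in self.noise_sd:
                raise RefstabError(f"no noise_sd for gene {g!r}")
        for name, value in [("loading_sd", self.loading_sd), ("tech_sd", self.tech_sd)]:
            if value < 0:
                raise RefstabError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise RefstabError("noise_sd values must be >= 0")

    @property
    def stable_genes(self) -> list[str]:
        return [
            g
            for g in self.genes
            if self.noise_sd[g] <= self.stable_threshold
            and not any(self.group_effects.get(g, {}).values())
        ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Realized ground truth returned alongside a simulated Cq table."""

    baseline_cq: pd.Series
    noise_sd: pd.Series
    group_effects: pd.DataFrame      # genes x treatments, cycles
    loading_effects: pd.Series       # per sample
    tech_sd: float
    stable_threshold: float
    seed: int

    @property
    def stable_genes(self) -> list[str]:
        quiet = self.noise_sd <= self.stable_threshold
        unshifted = (self.group_effects == 0).all(axis=1)
        return list(self.noise_sd.index[quiet & unshifted])

    @property
    def instability_order(self) -> list[str]:
        """Genes from most to least stable by total perturbation size."""
        score = np.sqrt(self.noise_sd**2 + (self.group_effects**2).mean(axis=1))
        return list(score.sort_values(kind="stable").index)


def reference_panel_config(
    n_genes: int = 10,
    best_sd: float = 0.05,
    stable_sd: float = 0.15,
    noisy_sd: float = 0.8,
    shift_cycles: float = 1.0,
    shifted_treatments: tuple[str, ...] = ("Pf", "DC3000"),
) -> CqSimConfig:
    """A study-shaped candidate panel with planted structure.

    Two near-perfect genes (the planted best pair), one gene responding
    to treatment by ``shift_cycles``, one high-noise gene, and moderately
    stable genes for the remainder.
    """
    if n_genes < 4:
        raise RefstabError("the planted panel needs at least 4 genes")
    genes = tuple(f"RG{i:02d}" for i in range(1, n_genes + 1))
    noise = {g: stable_sd for g in genes}
    noise[genes[0]] = best_sd
    noise[genes[1]] = best_sd
    noise[genes[-1]] = noisy_sd
    effects = {genes[-2]: {t: shift_cycles for t in shifted_treatments}}
    return CqSimConfig(genes=genes, noise_sd=noise, group_effects=effects)


def simulate_cq_dataset(
    config: CqSimConfig,
    design: Design = STUDY_DESIGN,
    seed: int = 0,
) -> tuple[CqTable, SyntheticTruth]:
    """Draw a full-factorial Cq table and return it with its truth."""
    rng = np.random.default_rng(seed)
    ann = design.annotations()
    genes = list(config.genes)

    if config.baseline_cq is None:
        baselines = pd.Series(rng.uniform(15.0, 30.0, len(genes)), index=genes)
    else:
        baselines = pd.Series({g: config.baseline_cq[g] for g in genes})
    loading = pd.Series(
        rng.normal(0.0, config.loading_sd, len(ann)), index=ann["sample_id"]
    )
    effects = pd.DataFrame(0.0, index=genes, columns=list(design.treatments))
    for g, shifts in config.group_effects.items():
        for treatment, shift in shifts.items():
            effects.loc[g, treatment] = shift

    rows = []
    for g in genes:
        sd = config.noise_sd[g]
        for _, sample in ann.iterrows():
            sid = sample["sample_id"]
            bio = rng.normal(0.0, sd) if sd > 0 else 0.0
            level = (
                baselines[g]
                + effects.loc[g, sample["group"]]
                + loading[sid]
                + bio
            )
            for tech in range(1, design.n_tech + 1):
                tech_noise = rng.normal(0.0, config.tech_sd) if config.tech_sd > 0 else 0.0
                rows.append((sid, g, tech, level + tech_noise))
    meas = pd.DataFrame(rows, columns=["sample_id", "gene", "tech_rep", "cq"])
    table = CqTable(meas, ann, collapsed=False)
    truth = SyntheticTruth(
        baseline_cq=baselines,
        noise_sd=pd.Series(config.noise_sd).loc[genes],
        group_effects=effects,
        loading_effects=loading,
        tech_sd=config.tech_sd,
        stable_threshold=config.stable_threshold,
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Expression matrix generator (screening input)
# ---------------------------------------------------------------------------

@dataclass
class ExprSimConfig:
    """Parameters for :func:`simulate_expression_table`.

    Baselines are lognormal (median ~ exp(log_mean) RPKM).  ``n_stable``
    genes get replicate CV ``stable_cv``; a ``low_fraction`` of genes is
    planted below the screening threshold; a ``de_fraction`` of the
    remainder receives treatment fold changes drawn from ``fold_range``;
    everything else varies with ``base_cv``.
    """

    n_genes: int = 500
    n_stable: int = 9
    stable_cv: float = 0.02
    base_cv: float = 0.25
    de_fraction: float = 0.3
    fold_range: tuple[float, float] = (2.0, 8.0)
    low_fraction: float = 0.1
    low_mean: float = 1.0
    log_mean: float = math.log(50.0)
    log_sd: float = 1.2
    treatments: tuple[str, ...] = ("mock", "Pf", "DC3000", "dHopQ1-1")
    n_bio: int = 3

    def __post_init__(self):
        for name, frac in [("de_fraction", self.de_fraction), ("low_fraction", self.low_fraction)]:
            if not 0.0 <= frac <= 1.0:
                raise RefstabError(f"{name} must lie in [0, 1]")
        if self.n_stable + int(self.low_fraction * self.n_genes) > self.n_genes:
            raise RefstabError("planted gene classes exceed n_genes")
        if min(self.stable_cv, self.base_cv) < 0:
            raise RefstabError("CVs must be >= 0")


@dataclass(frozen=True)
class ExpressionTruth:
    stable_genes: list[str]
    low_genes: list[str]
    de_genes: list[str]
    cv: pd.Series
    seed: int


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sd_log = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(-(sd_log**2) / 2.0, sd_log, size)


def simulate_expression_table(
    config: ExprSimConfig = ExprSimConfig(),
    seed: int = 0,
) -> tuple[ExpressionTable, ExpressionTruth]:
    """RPKM-like matrix with planted stable / low / DE genes."""
    rng = np.random.default_rng(seed)
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    n_low = int(round(config.low_fraction * n))
    stable = genes[: config.n_stable]
    low = genes[config.n_stable : config.n_stable + n_low]
    rest = genes[config.n_stable + n_low :]
    n_de = int(round(config.de_fraction * len(rest)))
    de = list(rng.choice(rest, size=n_de, replace=False))

    ann_rows = [
        {"sample_id": f"{t}_r{r}", "group": t, "timepoint": "6h", "bio_rep": r}
        for t in config.treatments
        for r in range(1, config.n_bio + 1)
    ]
    ann = pd.DataFrame(ann_rows)
    samples = list(ann["sample_id"])
    n_s = len(samples)

    baselines = rng.lognormal(config.log_mean, config.log_sd, n)
    # planted stable genes are reference-gene candidates: expressed by
    # construction, so their baselines stay clear of the low-RPKM filter
    for gi in range(len(stable)):
        while baselines[gi] < 10.0:
            baselines[gi] = rng.lognormal(config.log_mean, config.log_sd)
    cv = pd.Series(config.base_cv, index=genes)
    cv.loc[stable] = config.stable_cv
    values = np.empty((n, n_s))
    treatment_of = ann["group"].to_numpy()
    for gi, g in enumerate(genes):
        base = baselines[gi]
        if g in low:
            # planted sub-threshold gene: mean safely below the RPKM filter
            base = rng.uniform(0.05, 0.8 * config.low_mean + 0.8)
        folds = np.ones(n_s)
        if g in de:
            # fold change in a random non-mock treatment subset
            hit = rng.choice(config.treatments[1:], size=rng.integers(1, len(config.treatments)), replace=False)
            fold = rng.uniform(*config.fold_range)
            if rng.random() < 0.5:
                fold = 1.0 / fold
            folds = np.where(np.isin(treatment_of, hit), fold, 1.0)
        values[gi] = base * folds * _lognormal_noise(rng, cv[g], n_s)
    table = ExpressionTable(pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples), ann)
    truth = ExpressionTruth(stable_genes=stable, low_genes=low, de_genes=sorted(de), cv=cv, seed=seed)
    return table, truth


# ---------------------------------------------------------------------------
# Dilution series generator
# ---------------------------------------------------------------------------

#: The standard-curve dilution levels (1:5, 1:10, 1:100, 1:1000).
DEFAULT_DILUTIONS = (0.2, 0.1, 0.01, 0.001)


def simulate_dilution_series(
    true_e: float = 2.0,
    amounts: tuple[float, ...] = DEFAULT_DILUTIONS,
    noise_sd: float = 0.0,
    n_tech: int = 3,
    intercept_cq: float = 18.0,
    seed: int = 0,
    gene: str = "target",
) -> DilutionSeries:
    """Cq readings following Cq = intercept - log(amount)/log(E) + noise."""
    if not 1.0 < true_e <= 2.2:
        raise RefstabError("true_e must lie in (1, 2.2]")
    if noise_sd < 0:
        raise RefstabError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for a in amounts:
        expected = intercept_cq - math.log(a) / math.log(true_e)
        for _ in range(n_tech):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((a, expected + noise))
    return DilutionSeries(gene=gene, points=pd.DataFrame(rows, columns=["amount", "cq"]))
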