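"""Synthetic pooled-screen generator with known ground truth.

Emulates a genome-scale knockout library screened in a chemogenetic
design: a T0 baseline pool, a vehicle (mock) arm and one or more treated
arms, each with biological (and optionally technical) replicates.

The generative model, per guide g of gene G:

* T0 relative abundance ``a_g ~ lognormal(meanlog, sdlog)`` — library
  skew from cloning and infection;
* shared proliferation: both arms scale expected abundance by
  ``2^(f_G * doublings + drift_g)`` where ``f_G`` is the per-doubling
  fitness rate of gene G (negative for dropout) and ``drift_g`` is a
  per-guide log2 drift shared between arms (guide-level heterogeneity
  that cancels in the treated-minus-mock residual but spreads guides
  along the M-A abscissa);
* drug-gene interaction: the treated arm additionally scales by
  ``2^(i_G)`` with ``i_G`` the planted interaction effect in log2 units
  (positive = resistant, negative = sensitive);
* an optional smooth intensity-dependent bias ``bias_fn(A)`` added to the
  treated log2 expectation — the artifact the loess stage removes;
* sequencing: counts per sample are negative binomial with mean
  ``share * depth`` and inverse-dispersion ``nb_size`` (Poisson when
  nb_size = inf); technical replicates are independent redraws of the
  same expectations.

Randomness derives from one seed via per-sample substreams, so output is
reproducible and independent of sample evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix

TRUTH_COLUMNS = ["gene_id", "fitness_effect", "interaction_effect", "class"]


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate a 2,000-gene screen at
    4 guides/gene, 3 biological replicates, 500 expected reads per guide.

    ``frac_fitness``, ``frac_resistant`` and ``frac_sensitive`` are disjoint
    gene fractions and must sum to <= 1. Fitness rates are per population
    doubling (log2); interaction effects are total log2 over the screen.
    """

    n_genes: int = 2000
    guides_per_gene: int = 4
    n_controls: int = 100
    bio_reps: int = 3
    tech_reps: int = 1
    reads_per_guide: float = 500.0
    depth_per_sample: int | None = None  # overrides reads_per_guide * n_guides
    t0_meanlog: float = 0.0
    t0_sdlog: float = 0.5
    nb_size: float = 10.0
    doublings: float = 10.0
    frac_fitness: float = 0.15
    fitness_range: tuple[float, float] = (-0.4, -0.05)
    frac_resistant: float = 0.05
    resistant_effect: float = 1.5
    frac_sensitive: float = 0.05
    sensitive_effect: float = -1.5
    guide_drift_sd: float = 0.3
    bias_fn: Callable[[np.ndarray], np.ndarray] | None = None
    compound: str = "drugA"
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_fitness, self.frac_resistant, self.frac_sensitive)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValidationError("effect fractions must lie in [0,1] and sum to <= 1")
        for name in ("n_genes", "guides_per_gene", "bio_reps", "tech_reps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_controls < 0:
            raise ValidationError("n_controls must be >= 0")
        if self.depth_per_sample is not None and self.depth_per_sample <= 0:
            raise ValidationError("depth_per_sample must be positive")
        if self.reads_per_guide <= 0 or self.t0_sdlog < 0 or not self.nb_size > 0:
            raise ValidationError("scale parameters must be positive")

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_controls

    @property
    def depth(self) -> int:
        if self.depth_per_sample is not None:
            return int(self.depth_per_sample)
        return int(round(self.reads_per_guide * self.n_guides))


def fold_coverage(n_cells: float, n_guides: float) -> float:
    """Cells (or reads) per library guide — the screen's fold coverage.

    Pooled screens aim to maintain this above ~200 at every passage so
    guide abundances track clone fitness rather than sampling noise.
    """
    if n_guides <= 0:
        raise ValidationError("n_guides must be positive")
    return n_cells / n_guides


def make_bias(kind: str, amplitude: float = 0.5, scale: float = 1.0) -> Callable:
    """Named smooth A-dependent bias functions for configs: 'sine' or 'sigmoid'."""
    if kind == "sine":
        return lambda a: amplitude * np.sin(np.asarray(a, dtype=float) / scale)
    if kind == "sigmoid":
        return lambda a: amplitude * np.tanh(np.asarray(a, dtype=float) / scale)
    raise ValidationError(f"unknown bias kind {kind!r} (expected 'sine' or 'sigmoid')")


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    gene_ids = np.array([f"G{i:05d}" for i in range(1, cfg.n_genes + 1)])
    classes = np.full(cfg.n_genes, "null", dtype=object)
    fitness = np.zeros(cfg.n_genes)
    interaction = np.zeros(cfg.n_genes)

    n_fit = int(round(cfg.frac_fitness * cfg.n_genes))
    n_res = int(round(cfg.frac_resistant * cfg.n_genes))
    n_sen = int(round(cfg.frac_sensitive * cfg.n_genes))
    chosen = rng.choice(cfg.n_genes, size=n_fit + n_res + n_sen, replace=False)
    fit_idx, res_idx, sen_idx = np.split(chosen, [n_fit, n_fit + n_res])
    classes[fit_idx] = "fitness_only"
    fitness[fit_idx] = rng.uniform(*cfg.fitness_range, size=n_fit)
    classes[res_idx] = "resistant"
    interaction[res_idx] = cfg.resistant_effect
    classes[sen_idx] = "sensitive"
    interaction[sen_idx] = cfg.sensitive_effect
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "fitness_effect": fitness,
            "interaction_effect": interaction,
            "class": classes,
        }
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if math.isinf(size):
        return rng.poisson(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen(cfg: SimConfig):
    """Generate one simulated screen.

    Returns ``(counts, samples, library, truth)``: a validated
    :class:`~chemoscreen.io.CountMatrix` (which embeds the sample sheet and
    guide library, also returned separately for convenience) and the
    planted per-gene truth table.
    """
    counts, truths = _simulate(cfg, [cfg.compound], shared_resistant=0, shared_sensitive=0)
    truth = truths[cfg.compound]
    return counts, counts.samples, counts.library, truth


def simulate_panel(
    cfg: SimConfig,
    compounds: list[str],
    shared_resistant: int = 0,
    shared_sensitive: int = 0,
):
    """Simulate several compounds against one shared T0/mock, with
    ``shared_*`` genes planted in the same direction in *all* compounds
    (the non-specific genes) and the remaining interaction genes drawn
    independently per compound.

    Returns ``(counts, truths)`` with one truth table per compound.
    """
    if len(compounds) != len(set(compounds)) or not compounds:
        raise ValidationError("compounds must be a non-empty list of unique names")
    return _simulate(cfg, compounds, shared_resistant, shared_sensitive)


def _simulate(cfg: SimConfig, compounds: list[str], shared_resistant: int, shared_sensitive: int):
    ss = np.random.SeedSequence(cfg.seed)
    struct_seed, samples_seed = ss.spawn(2)
    rng = np.random.default_rng(struct_seed)

    # library and per-guide structure
    gene_ids = np.array([f"G{i:05d}" for i in range(1, cfg.n_genes + 1)])
    guide_gene = np.repeat(gene_ids, cfg.guides_per_gene)
    ctrl_genes = np.array([f"CTRL{i:04d}" for i in range(1, cfg.n_controls + 1)])
    all_genes_per_guide = np.concatenate([guide_gene, ctrl_genes])
    guide_ids = np.array(
        [f"{g}_sg{i % cfg.guides_per_gene + 1}" for i, g in enumerate(guide_gene)]
        + [f"{g}_sg1" for g in ctrl_genes]
    )
    library = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "gene_id": all_genes_per_guide,
            "is_control": np.concatenate(
                [np.zeros(len(guide_gene), dtype=bool), np.ones(len(ctrl_genes), dtype=bool)]
            ),
        }
    )

    n_guides = cfg.n_guides
    a0 = rng.lognormal(cfg.t0_meanlog, cfg.t0_sdlog, size=n_guides)
    drift = rng.normal(0.0, cfg.guide_drift_sd, size=n_guides)

    # truth: shared fitness background; non-specific (shared) interaction
    # genes planted in all compounds; the rest drawn independently per compound
    base_truth = _draw_truth(replace(cfg, frac_resistant=0.0, frac_sensitive=0.0), rng)
    pool = np.flatnonzero(base_truth["class"].to_numpy() == "null")
    if shared_resistant + shared_sensitive > len(pool):
        raise ValidationError("not enough null genes for the requested shared hits")
    shared = rng.choice(pool, size=shared_resistant + shared_sensitive, replace=False)
    sh_res, sh_sen = shared[:shared_resistant], shared[shared_resistant:]
    n_res = max(int(round(cfg.frac_resistant * cfg.n_genes)) - shared_resistant, 0)
    n_sen = max(int(round(cfg.frac_sensitive * cfg.n_genes)) - shared_sensitive, 0)

    truths: dict[str, pd.DataFrame] = {}
    for compound in compounds:
        t = base_truth.copy()
        pool_k = np.setdiff1d(pool, shared, assume_unique=False)
        pick = rng.choice(pool_k, size=n_res + n_sen, replace=False)
        res_idx = np.concatenate([sh_res, pick[:n_res]])
        sen_idx = np.concatenate([sh_sen, pick[n_res:]])
        t.loc[res_idx, "class"] = "resistant"
        t.loc[res_idx, "interaction_effect"] = cfg.resistant_effect
        t.loc[sen_idx, "class"] = "sensitive"
        t.loc[sen_idx, "interaction_effect"] = cfg.sensitive_effect
        truths[compound] = t

    gene_index = pd.Series(np.arange(cfg.n_genes), index=gene_ids)
    tgt = ~library["is_control"].to_numpy()
    gpos = gene_index.loc[library.loc[tgt, "gene_id"]].to_numpy()

    def per_guide(vec_per_gene: np.ndarray) -> np.ndarray:
        out = np.zeros(n_guides)
        out[tgt] = vec_per_gene[gpos]
        return out

    fitness_g = per_guide(base_truth["fitness_effect"].to_numpy())
    shared_log2 = fitness_g * cfg.doublings + drift  # both arms

    # expected abundances per condition
    expectations: dict[str, np.ndarray] = {"T0": a0}
    expectations["mock"] = a0 * np.exp2(shared_log2)
    for compound in compounds:
        inter_g = per_guide(truths[compound]["interaction_effect"].to_numpy())
        treated_log2 = shared_log2 + inter_g
        if cfg.bias_fn is not None:
            a_true = (shared_log2 + treated_log2) / 2.0
            treated_log2 = treated_log2 + np.asarray(cfg.bias_fn(a_true), dtype=float)
        expectations[f"treated:{compound}"] = a0 * np.exp2(treated_log2)

    # sample sheet: T0 per bio rep, then mock/treated x bio x tech
    rows = []
    for b in range(1, cfg.bio_reps + 1):
        rows.append((f"T0_b{b}", "T0", None, b, 1, "T0"))
    for b in range(1, cfg.bio_reps + 1):
        for tr in range(1, cfg.tech_reps + 1):
            rows.append((f"mock_b{b}_t{tr}", "mock", None, b, tr, "mock"))
    for compound in compounds:
        for b in range(1, cfg.bio_reps + 1):
            for tr in range(1, cfg.tech_reps + 1):
                rows.append(
                    (f"{compound}_b{b}_t{tr}", "treated", compound, b, tr, f"treated:{compound}")
                )
    sheet = pd.DataFrame(
        [r[:5] for r in rows],
        columns=["sample_id", "arm", "compound", "bio_rep", "tech_rep"],
    )

    depth = cfg.depth
    child_seeds = samples_seed.spawn(len(rows))
    count_cols = {}
    for (sample_id, *_, cond), child in zip(rows, child_seeds):
        srng = np.random.default_rng(child)
        w = expectations[cond]
        mean = w / w.sum() * depth
        count_cols[sample_id] = _nb_counts(srng, mean, cfg.nb_size)
    counts = pd.DataFrame(count_cols, index=pd.Index(guide_ids, name="guide_id"))
    cm = CountMatrix(library=library, samples=sheet, counts=counts)
    return cm, truths


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    """Hit recovery against planted truth.

    Recalls are per planted class (NaN when no gene of that class was
    planted); ``empirical_fdr`` is the fraction of called hits whose
    direction does not match the planted interaction (0 when nothing was
    called); ``sign_accuracy`` is the fraction of hits on interaction genes
    with the correct direction.
    """

    recall_resistant: float
    recall_sensitive: float
    empirical_fdr: float
    sign_accuracy: float


def evaluate_recovery(scores: pd.DataFrame, truth: pd.DataFrame) -> RecoveryMetrics:
    """Compare called hits with planted truth on a shared gene universe."""
    unknown = set(scores["gene_id"]) - set(truth["gene_id"])
    if unknown:
        raise ValidationError(f"scored gene {sorted(unknown)[0]!r} is not in the truth table")
    merged = scores[["gene_id", "hit_class"]].merge(truth, on="gene_id", how="right")
    merged["hit_class"] = merged["hit_class"].fillna("none")

    cls = merged["class"].to_numpy()
    call = merged["hit_class"].to_numpy()

    def recall(label: str) -> float:
        true = cls == label
        if not true.any():
            return float("nan")
        return float((true & (call == label)).sum() / true.sum())

    hits = call != "none"
    correct = hits & (call == cls)
    n_hits = int(hits.sum())
    efdr = 0.0 if n_hits == 0 else float((hits & ~correct).sum() / n_hits)
    on_inter = hits & np.isin(cls, ["resistant", "sensitive"])
    sign_acc = float("nan") if not on_inter.any() else float(correct[on_inter].sum() / on_inter.sum())
    return RecoveryMetrics(
        recall_resistant=recall("resistant"),
        recall_sensitive=recall("sensitive"),
        empirical_fdr=efdr,
        sign_accuracy=sign_acc,
    )
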