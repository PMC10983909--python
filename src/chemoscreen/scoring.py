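"""Scoring of pooled chemogenetic CRISPR screens.

The pipeline turns raw guide read counts into per-gene drug–gene
interaction calls:

1. depth normalization to counts-per-million;
2. log2 fold change (LFC) of each sample against the T0 baseline;
3. guide filter (raw T0 counts >= 30) and gene filter (>= 3 surviving
   guides);
4. averaging of technical-replicate LFCs;
5. residual effects per guide x biological replicate:
   M = treated LFC - mock LFC (the drug-specific component) and
   A = (treated + mock)/2 (the M-A abscissa);
6. loess normalization of M against A, removing intensity-dependent bias;
7. empirical-Bayes moderated one-sample t-test on the normalized residuals
   pooled per gene, with the variance prior (d0, s0^2) estimated across all
   genes by the method of moments on log variances;
8. Benjamini-Hochberg FDR and hit calling at |effect| > 0.5 and q < 0.4
   (strict inequalities);
9. cross-compound specificity: a gene hit in the same direction in every
   compound is flagged non-specific.

The moderated t shrinks each gene's sample variance s_g^2 (d_g = n_g - 1
degrees of freedom) toward the prior: s~^2 = (d0*s0^2 + d_g*s_g^2)/(d0+d_g),
t = effect / sqrt(s~^2 / n_g), with d0 + d_g total degrees of freedom.
d0 = 0 collapses to the ordinary one-sample t; d0 = inf to a z-statistic
with variance s0^2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import NumericalError, ValidationError
from .io import CountMatrix

logger = logging.getLogger("chemoscreen")

RESIDUAL_COLUMNS = ["guide_id", "gene_id", "compound", "bio_rep", "M", "A", "M_norm"]


@dataclass
class NormalizedMatrix:
    """Depth-normalized guide abundances (counts-per-million scale)."""

    values: pd.DataFrame
    samples: pd.DataFrame
    library: pd.DataFrame
    scale: float = 1e6


@dataclass
class LFCTable:
    """Per-guide log2 fold changes vs the T0 baseline.

    ``lfc`` is guides x samples; ``samples`` carries per-column metadata
    (after technical-replicate averaging, one column per arm/compound/
    bio_rep and ``tech_rep`` is 1).
    """

    lfc: pd.DataFrame
    samples: pd.DataFrame
    library: pd.DataFrame


@dataclass
class VariancePrior:
    """Empirical-Bayes prior for gene variances: s_g^2 ~ s0^2 * d0 / chi^2_d0.

    d0 may be 0 (no moderation, ordinary t) or math.inf (complete pooling,
    z-statistic against s0^2).
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0 or not self.s0_sq > 0:
            raise ValidationError("variance prior requires d0 >= 0 and s0_sq > 0")


@dataclass
class ScoreParams:
    """All tunable stage parameters with the pipeline's default operating point."""

    min_t0: int = 30
    min_guides: int = 3
    pseudocount: float = 0.5
    scale: float = 1e6
    span: float = 0.3
    loess_degree: int = 1
    robust_iters: int = 4
    effect_cut: float = 0.5
    fdr_cut: float = 0.4


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def normalize_depth(counts: CountMatrix, scale: float = 1e6) -> NormalizedMatrix:
    """Scale each sample to ``scale`` total (counts-per-million for 1e6)."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total read count")
    values = counts.counts / totals * scale
    return NormalizedMatrix(values=values, samples=counts.samples, library=counts.library, scale=scale)


def guide_lfc(norm: NormalizedMatrix, sheet: pd.DataFrame | None = None, pseudocount: float = 0.5) -> LFCTable:
    """log2((norm + pseudocount) / (T0 + pseudocount)) per guide and sample.

    Multiple T0 samples are averaged on the normalized scale first.
    """
    sheet = norm.samples if sheet is None else sheet
    t0_ids = sheet.loc[sheet["arm"] == "T0", "sample_id"]
    if t0_ids.empty:
        raise ValidationError("no T0 sample in the sample sheet")
    baseline = norm.values[list(t0_ids)].mean(axis=1)
    lfc = np.log2(norm.values.add(pseudocount, axis=0).div(baseline + pseudocount, axis=0))
    return LFCTable(lfc=lfc, samples=sheet, library=norm.library)


def filter_guides(counts: CountMatrix, min_t0: int = 30) -> pd.DataFrame:
    """Keep guides whose raw T0 count (mean over T0 samples) is >= min_t0."""
    t0_ids = counts.samples.loc[counts.samples["arm"] == "T0", "sample_id"]
    if t0_ids.empty:
        raise ValidationError("no T0 sample in the sample sheet")
    t0_mean = counts.counts[list(t0_ids)].mean(axis=1)
    keep = (t0_mean >= min_t0).to_numpy()
    return pd.DataFrame(
        {
            "guide_id": counts.library["guide_id"].to_numpy(),
            "keep": keep,
            "reason": np.where(keep, "kept", "low_T0"),
        }
    )


def filter_genes(mask: pd.DataFrame, lib: pd.DataFrame, min_guides: int = 3) -> pd.DataFrame:
    """Keep genes with >= min_guides surviving guides; controls never form genes."""
    if set(lib["guide_id"]) - set(mask["guide_id"]):
        raise ValidationError("guide mask does not cover all library guides")
    merged = lib.merge(mask[["guide_id", "keep"]], on="guide_id", how="left")
    merged = merged[~merged["is_control"]]
    surviving = merged.groupby("gene_id", sort=True)["keep"].sum()
    keep = (surviving >= min_guides).to_numpy()
    return pd.DataFrame(
        {
            "gene_id": surviving.index.to_numpy(),
            "keep": keep,
            "reason": np.where(keep, "kept", "too_few_guides"),
        }
    )


def average_technical_replicates(lfc: LFCTable, sheet: pd.DataFrame | None = None) -> LFCTable:
    """Arithmetic mean of LFCs over technical replicates.

    Returns an LFCTable with one column per (arm, compound, bio_rep); a
    single technical replicate passes through unchanged.
    """
    sheet = lfc.samples if sheet is None else sheet
    key_cols = ["arm", "compound", "bio_rep"]
    groups = sheet.fillna({"compound": ""}).groupby(key_cols, sort=False)
    cols, meta = {}, []
    for (arm, compound, bio_rep), members in groups:
        new_id = f"{arm}|{compound}|{bio_rep}"
        cols[new_id] = lfc.lfc[list(members["sample_id"])].mean(axis=1)
        meta.append(
            {
                "sample_id": new_id,
                "arm": arm,
                "compound": compound or None,
                "bio_rep": int(bio_rep),
                "tech_rep": 1,
            }
        )
    return LFCTable(lfc=pd.DataFrame(cols), samples=pd.DataFrame(meta), library=lfc.library)


def residual_effects(lfc: LFCTable, compound: str) -> pd.DataFrame:
    """Per guide x bio_rep: M = treated - mock LFC, A = their mean.

    ``lfc`` must already be technical-replicate averaged. A mock sample with
    a null compound (shared vehicle arm) matches any compound; an explicit
    compound matches only itself. Returns a long residual table with M_norm
    unset (NaN) until loess normalization.
    """
    sheet = lfc.samples
    treated = sheet[(sheet["arm"] == "treated") & (sheet["compound"] == compound)]
    if treated.empty:
        raise ValidationError(f"no treated samples for compound {compound!r}")
    mock = sheet[sheet["arm"] == "mock"]
    pieces = []
    gene_ids = lfc.library.set_index("guide_id")["gene_id"]
    for _, row in treated.sort_values("bio_rep").iterrows():
        partners = mock[
            (mock["bio_rep"] == row["bio_rep"])
            & (mock["compound"].isna() | (mock["compound"] == compound))
        ]
        if partners.empty:
            raise ValidationError(
                f"treated bio_rep {row['bio_rep']} of {compound!r} has no matching mock sample"
            )
        t_vals = lfc.lfc[row["sample_id"]]
        m_vals = lfc.lfc[list(partners["sample_id"])].mean(axis=1)
        pieces.append(
            pd.DataFrame(
                {
                    "guide_id": t_vals.index,
                    "gene_id": gene_ids.loc[t_vals.index].to_numpy(),
                    "compound": compound,
                    "bio_rep": int(row["bio_rep"]),
                    "M": (t_vals - m_vals).to_numpy(),
                    "A": ((t_vals + m_vals) / 2.0).to_numpy(),
                    "M_norm": np.nan,
                }
            )
        )
    res = pd.concat(pieces, ignore_index=True)
    if not np.isfinite(res["A"]).all():
        raise ValidationError("non-finite A values in residual table")
    return res


def loess_normalize(
    res: pd.DataFrame,
    span: float = 0.3,
    degree: int = 1,
    robust_iters: int = 4,
    delta: float | None = None,
) -> pd.DataFrame:
    """Remove the smooth trend of M on A by robust loess; M_norm = M - fit(A).

    Locally weighted linear regression with tricube weights over the
    ``span`` fraction of nearest neighbours and ``robust_iters``
    Tukey-biweight robustifying iterations, fit separately per compound
    with biological replicates pooled. ``delta=None`` picks the standard
    speedup ``0.01 * range(A)`` (exact fits are linearly interpolated
    between close A values); pass ``delta=0`` for the exact smoother at
    every point.
    """
    if degree != 1:
        raise ValidationError("only locally linear loess (degree=1) is supported")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out = res.copy()
    for compound, idx in res.groupby("compound", sort=False).groups.items():
        a = res.loc[idx, "A"].to_numpy(dtype=float)
        m = res.loc[idx, "M"].to_numpy(dtype=float)
        n = len(a)
        if n < 10:
            raise ValidationError(f"loess needs >= 10 rows, got {n} for compound {compound!r}")
        if np.ptp(a) == 0:
            raise ValidationError(f"all A values identical for compound {compound!r}")
        window = int(math.ceil(span * n))
        if window < degree + 1:
            raise ValidationError(
                f"span {span} covers only {window} point(s) of {n}; increase the span"
            )
        d = 0.01 * np.ptp(a) if delta is None else delta
        fitted = lowess(m, a, frac=span, it=robust_iters, delta=d, return_sorted=False)
        out.loc[idx, "M_norm"] = m - fitted
    return out


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_variance_prior(s_sq, d) -> VariancePrior:
    """Estimate the variance prior (d0, s0^2) across genes.

    Method of moments on log variances: with
    ``e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2)``, the excess spread of
    e_g over its sampling component identifies trigamma(d0/2); d0 is then
    recovered by Newton inversion and s0^2 from mean(e_g). When the spread
    target is <= 0 (gene variances no more dispersed than chance) the prior
    degenerates to d0 = inf, s0^2 = exp(mean(e_g)).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.asarray(d, dtype=float)
    if s_sq.shape != d.shape:
        raise ValidationError("s_sq and d must have the same length")
    ok = (d >= 1) & (s_sq > 0)
    if (~np.isfinite(s_sq)).any():
        raise ValidationError("variances must be finite")
    if not (s_sq > 0).any():
        raise ValidationError("all gene variances are zero; cannot fit a variance prior")
    s_sq, d = s_sq[ok], d[ok]
    n = len(s_sq)
    if n < 20:
        raise ValidationError(f"need >= 20 genes with d >= 1 and s_sq > 0, got {n}")

    e = np.log(s_sq) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    target = e_var - float(np.mean(special.polygamma(1, d / 2.0)))
    if target <= 0:
        # zero excess spread: complete pooling; the prior variance is the
        # (arithmetic) mean variance so identical inputs return themselves
        return VariancePrior(d0=math.inf, s0_sq=float(s_sq.mean()))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(res: pd.DataFrame, prior: VariancePrior, min_obs: int = 2) -> pd.DataFrame:
    """Per-gene moderated one-sample t-test on normalized residuals.

    Observations are guide x bio_rep M_norm values pooled per gene. Genes
    with fewer than ``min_obs`` observations are excluded with a warning.
    Returns a gene-score table (q and hit_class filled by later stages).
    """
    if res["M_norm"].isna().any():
        raise ValidationError("M_norm is unset; run loess_normalize first")
    grouped = res.groupby("gene_id", sort=True)["M_norm"]
    n_obs = grouped.size()
    too_few = n_obs[n_obs < min_obs]
    if len(too_few):
        warnings.warn(
            f"{len(too_few)} gene(s) with fewer than {min_obs} residuals excluded from scoring "
            f"(first: {too_few.index[0]!r})",
            stacklevel=2,
        )
    kept = n_obs[n_obs >= min_obs].index
    sub = res[res["gene_id"].isin(kept)]
    g = sub.groupby("gene_id", sort=True)
    n = g["M_norm"].size().to_numpy(dtype=float)
    effect = g["M_norm"].mean().to_numpy()
    s_sq = g["M_norm"].var(ddof=1).to_numpy()
    n_guides = g["guide_id"].nunique().to_numpy()
    d_g = n - 1.0

    d0, s0 = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s_post = np.full_like(s_sq, s0)
        df = np.full_like(s_sq, math.inf)
    else:
        s_post = (d0 * s0 + d_g * s_sq) / (d0 + d_g)
        df = d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s_post / n)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: zero effect with zero variance
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "gene_id": g.size().index.to_numpy(),
            "n_guides": n_guides.astype(int),
            "n_obs": n.astype(int),
            "effect": effect,
            "s_sq": s_sq,
            "t": t,
            "df": df,
            "p": p,
            "q": np.nan,
            "hit_class": "none",
        }
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{p_j >= p_i} m p_j / rank_j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a non-empty 1-d array")
    if (~np.isfinite(p)).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_hits(scores: pd.DataFrame, effect_cut: float = 0.5, fdr_cut: float = 0.4) -> pd.DataFrame:
    """Classify hits with strict inequalities: resistant if effect > effect_cut
    and q < fdr_cut; sensitive if effect < -effect_cut and q < fdr_cut."""
    out = scores.copy()
    q = out["q"].to_numpy(dtype=float)
    eff = out["effect"].to_numpy(dtype=float)
    hit = q < fdr_cut
    out["hit_class"] = np.select(
        [hit & (eff > effect_cut), hit & (eff < -effect_cut)],
        ["resistant", "sensitive"],
        default="none",
    )
    return out


def classify_specificity(per_compound: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-compound specificity of hit calls.

    non_specific: hit with the same direction in every compound (excluded);
    compound_specific: hit in exactly one; shared_subset: hit in two or more
    but not same-direction-in-all; none otherwise.
    """
    if len(per_compound) < 2:
        raise ValidationError("specificity needs at least two compounds")
    names = sorted(per_compound)
    universes = [tuple(sorted(per_compound[c]["gene_id"])) for c in names]
    if len(set(universes)) != 1:
        raise ValidationError("gene universes differ between compounds")
    wide = pd.DataFrame({"gene_id": sorted(universes[0])})
    for c in names:
        calls = per_compound[c].set_index("gene_id")["hit_class"]
        wide[f"hit_{c}"] = calls.loc[wide["gene_id"]].to_numpy()
    calls = wide[[f"hit_{c}" for c in names]].to_numpy()
    n_hits = (calls != "none").sum(axis=1)
    all_same_dir = (calls == "resistant").all(axis=1) | (calls == "sensitive").all(axis=1)
    wide["specificity"] = np.select(
        [all_same_dir, n_hits == 1, n_hits >= 2],
        ["non_specific", "compound_specific", "shared_subset"],
        default="none",
    )
    wide["excluded"] = wide["specificity"] == "non_specific"
    return wide


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def score_screen(
    counts: CountMatrix,
    params: ScoreParams | None = None,
    compounds: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full scoring pipeline; returns one gene-score table per compound."""
    params = params or ScoreParams()
    sheet = counts.samples
    if compounds is None:
        compounds = sorted(sheet.loc[sheet["arm"] == "treated", "compound"].dropna().unique())
    if not compounds:
        raise ValidationError("no treated compounds in the sample sheet")

    gmask = filter_guides(counts, params.min_t0)
    gene_mask = filter_genes(gmask, counts.library, params.min_guides)
    kept_guides = set(gmask.loc[gmask["keep"], "guide_id"])
    kept_genes = set(gene_mask.loc[gene_mask["keep"], "gene_id"])
    logger.info(
        "filters: %d/%d guides kept (min_t0=%d), %d/%d genes kept (min_guides=%d)",
        len(kept_guides), len(gmask), params.min_t0,
        len(kept_genes), len(gene_mask), params.min_guides,
    )

    norm = normalize_depth(counts, params.scale)
    lfc = guide_lfc(norm, pseudocount=params.pseudocount)
    avg = average_technical_replicates(lfc)
    logger.info("LFC: %d guides x %d averaged conditions", *avg.lfc.shape)

    controls = set(counts.library.loc[counts.library["is_control"], "guide_id"])
    results: dict[str, pd.DataFrame] = {}
    for compound in compounds:
        res = residual_effects(avg, compound)
        res = res[
            res["guide_id"].isin(kept_guides)
            & ~res["guide_id"].isin(controls)
            & res["gene_id"].isin(kept_genes)
        ].reset_index(drop=True)
        logger.info("%s: %d residuals (guide x bio_rep) enter loess", compound, len(res))
        res = loess_normalize(
            res, span=params.span, degree=params.loess_degree, robust_iters=params.robust_iters
        )
        stats_g = res.groupby("gene_id")["M_norm"].agg(["var", "size"])
        usable = stats_g[(stats_g["size"] >= 2) & (stats_g["var"] > 0)]
        if usable.empty:
            # all residuals identical per gene (e.g. treated == mock):
            # effects are exactly 0, so the prior scale is immaterial
            prior = VariancePrior(d0=math.inf, s0_sq=1.0)
        else:
            prior = fit_variance_prior(usable["var"].to_numpy(), usable["size"].to_numpy() - 1.0)
        logger.info("%s: variance prior d0=%.3g s0_sq=%.4g", compound, prior.d0, prior.s0_sq)
        scores = moderated_t(res, prior)
        scores["q"] = bh_fdr(scores["p"].to_numpy())
        scores = call_hits(scores, params.effect_cut, params.fdr_cut)
        n_res = int((scores["hit_class"] == "resistant").sum())
        n_sen = int((scores["hit_class"] == "sensitive").sum())
        logger.info("%s: %d genes scored, %d resistant / %d sensitive hits",
                    compound, len(scores), n_res, n_sen)
        results[compound] = scores
    return results
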