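"""Trans-eQTL and co-expression screening with cross-mappability flags.

The screen mirrors the standard artifact-audit workflow: test
inter-chromosomal variant-gene pairs with an ordinary-least-squares
linear model (expression ~ genotype + covariates), adjust p-values with
Benjamini-Hochberg, flag every trans association whose target gene
receives cross-mapping from some gene near the variant, and re-assess
FDR after removing flagged tests. Co-expression utilities compare
absolute Pearson correlations of residualised expression between
cross-mappable and non-cross-mappable gene pairs.

Flagging never alters a p-value; it only changes which tests enter the
filtered multiple-testing pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, genes_near_position
from .crossmap import CrossmapResource, is_crossmappable
from .intervals import IntervalSet

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_MAF_MIN = 0.05


# ---------------------------------------------------------------------------
# variant filtering and pair classification
# ---------------------------------------------------------------------------

def filter_variants(
    variants: pd.DataFrame,
    repeat_intervals: Optional[Mapping[str, IntervalSet]] = None,
    maf_min: float = DEFAULT_MAF_MIN,
) -> pd.DataFrame:
    """Keep variants with maf >= maf_min whose position is not in a repeat.

    ``variants`` needs columns variant_id, chrom, pos, maf.
    """
    keep = variants["maf"] >= maf_min
    if repeat_intervals is not None:
        in_repeat = variants.apply(
            lambda row: row["chrom"] in repeat_intervals
            and repeat_intervals[row["chrom"]].contains(int(row["pos"])),
            axis=1,
        )
        keep &= ~in_repeat
    return variants.loc[keep].reset_index(drop=True)


def classify_pair(
    variant_chrom: str,
    variant_pos: int,
    gene_model: GeneModel,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> str:
    """cis if within cis_window of the gene's TSS on the same chromosome,
    trans if on different chromosomes, other otherwise."""
    if variant_chrom != gene_model.chrom:
        return "trans"
    return "cis" if abs(variant_pos - gene_model.tss) <= cis_window else "other"


# ---------------------------------------------------------------------------
# association testing
# ---------------------------------------------------------------------------

def linear_association(
    genotype: np.ndarray,
    expression_row: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> Tuple[float, float, float]:
    """OLS of expression on genotype + covariates + intercept.

    Returns (beta, t-statistic, two-sided p) for the genotype coefficient.
    ``covariates`` is covariates x samples. Constant genotype is an error
    (callers skip and log such records).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    n = len(g)
    if np.ptp(g) == 0:
        raise ValueError("constant genotype: association undefined")
    cols = [np.ones(n), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        cols.extend(C)
    X = np.column_stack(cols)
    if n < X.shape[1] + 1:
        raise ValueError("too few samples for the model")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = float(coef[1])
    if se == 0:
        return beta, np.inf if beta > 0 else -np.inf, 0.0
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(t), float(p)


def residualize(
    expression: pd.DataFrame, covariates: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-gene OLS residuals against covariates + intercept (genes x samples).

    With no covariates this centres each gene. Residuals are orthogonal to
    every covariate. Rank-deficient covariates are an error.
    """
    Y = expression.to_numpy(dtype=float)
    n = Y.shape[1]
    cols = [np.ones(n)]
    if covariates is not None and len(covariates) > 0:
        if list(covariates.columns) != list(expression.columns):
            covariates = covariates[expression.columns]
        cols.extend(covariates.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    R = Y - (X @ coef).T
    return pd.DataFrame(R, index=expression.index, columns=expression.columns)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_trans_scan(
    genotypes: pd.DataFrame,
    variant_info: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    models: Mapping[str, GeneModel],
    cis_window: int = DEFAULT_CIS_WINDOW,
    classes: Tuple[str, ...] = ("trans",),
) -> pd.DataFrame:
    """Association tests for every variant-gene pair in the given classes.

    ``genotypes``: variants x samples dosages indexed by variant_id;
    ``variant_info``: variant_id, chrom, pos; ``expression``: genes x
    samples. The whole matrix is tested at once: genotype and expression
    are residualised against covariates + intercept, and the t-statistic
    of each pair follows from their correlation (identical to per-pair
    OLS by the Frisch-Waugh theorem; the equivalence is asserted in the
    test suite). Returns variant_id, gene_id, eqtl_class, beta,
    statistic, p, fdr (BH across the returned tests).
    """
    if list(genotypes.columns) != list(expression.columns):
        genotypes = genotypes[expression.columns]
    n = expression.shape[1]
    n_cov = 0 if covariates is None else len(covariates)
    df = n - n_cov - 2
    if df < 1:
        raise ValueError("too few samples for the model")

    Gr = residualize(genotypes, covariates).to_numpy()
    Er = residualize(expression, covariates).to_numpy()
    g_ss = (Gr**2).sum(axis=1)
    e_ss = (Er**2).sum(axis=1)
    const = g_ss == 0
    if const.any():
        logger.warning("%d constant-genotype variants skipped", const.sum())

    info = variant_info.set_index("variant_id")
    rows: List[dict] = []
    for vi, variant_id in enumerate(genotypes.index):
        if const[vi]:
            continue
        vchrom = info.at[variant_id, "chrom"]
        vpos = int(info.at[variant_id, "pos"])
        dots = Er @ Gr[vi]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = dots / np.sqrt(e_ss * g_ss[vi])
        for gi, gene_id in enumerate(expression.index):
            klass = classify_pair(vchrom, vpos, models[gene_id], cis_window)
            if klass not in classes:
                continue
            if e_ss[gi] == 0:
                logger.warning("constant expression for %s skipped", gene_id)
                continue
            r_ig = min(max(r[gi], -1.0), 1.0)
            if abs(r_ig) >= 1.0:
                t_stat = np.inf * np.sign(r_ig)
                p = 0.0
            else:
                t_stat = r_ig * np.sqrt(df / (1.0 - r_ig**2))
                p = 2.0 * stats.t.sf(abs(t_stat), df)
            beta = dots[gi] / g_ss[vi]
            rows.append(
                dict(
                    variant_id=variant_id,
                    gene_id=gene_id,
                    eqtl_class=klass,
                    beta=beta,
                    statistic=t_stat,
                    p=p,
                )
            )
    out = pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "eqtl_class", "beta", "statistic", "p"]
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# cross-mappability flagging and FDR reassessment
# ---------------------------------------------------------------------------

def flag_trans_eqtls(
    associations: pd.DataFrame,
    models: Iterable[GeneModel],
    resource: CrossmapResource,
    variant_info: pd.DataFrame,
    window_bp: int = DEFAULT_CIS_WINDOW,
    direction: str = "either",
) -> pd.DataFrame:
    """Set ``crossmappable`` on each association: true iff some gene with
    TSS within window_bp of the variant cross-maps to the target gene."""
    models = list(models)
    known = {m.gene_id for m in models}
    missing = set(associations["gene_id"]) - known
    if missing:
        raise KeyError(f"target genes absent from models: {sorted(missing)[:5]}")
    info = variant_info.set_index("variant_id")
    out = associations.copy()
    flags = []
    cache: Dict[str, frozenset] = {}
    for variant_id, target in zip(out["variant_id"], out["gene_id"]):
        if variant_id not in cache:
            cache[variant_id] = frozenset(
                genes_near_position(
                    models,
                    info.at[variant_id, "chrom"],
                    int(info.at[variant_id, "pos"]),
                    window_bp,
                )
            )
        flags.append(
            any(
                g != target and is_crossmappable(resource, g, target, direction)
                for g in cache[variant_id]
            )
        )
    out["crossmappable"] = flags
    return out


@dataclass
class ReassessResult:
    original: pd.DataFrame  # significant under BH over all tests
    filtered: pd.DataFrame  # significant under BH over unflagged tests only
    n_original: int
    n_filtered: int
    n_genes_original: int
    n_genes_filtered: int


def refilter_and_reassess(associations: pd.DataFrame, alpha: float) -> ReassessResult:
    """Significant sets before and after removing flagged tests.

    BH is recomputed on the unflagged subset: dropping prevalent potential
    false positives changes every adjusted value, so the filtered
    significant set is not simply the unflagged members of the original.
    """
    assoc = associations.reset_index(drop=True)
    fdr_all = bh_fdr(assoc["p"].to_numpy()) if len(assoc) else np.array([])
    original = assoc.loc[fdr_all <= alpha].copy()
    original["fdr"] = fdr_all[fdr_all <= alpha]

    unflagged = assoc.loc[~assoc["crossmappable"].astype(bool)].copy()
    fdr_sub = bh_fdr(unflagged["p"].to_numpy()) if len(unflagged) else np.array([])
    filtered = unflagged.loc[fdr_sub <= alpha].copy()
    filtered["fdr"] = fdr_sub[fdr_sub <= alpha]

    return ReassessResult(
        original=original,
        filtered=filtered,
        n_original=len(original),
        n_filtered=len(filtered),
        n_genes_original=original["gene_id"].nunique(),
        n_genes_filtered=filtered["gene_id"].nunique(),
    )


def top_hit_crossmap_fraction(
    associations: pd.DataFrame,
) -> Tuple[np.ndarray, float]:
    """Cumulative flagged fraction among top-ranked tests, plus background.

    Tests are ranked by increasing p (ties broken by variant_id, gene_id);
    element r-1 of the curve is the flagged fraction of the top r. The
    background is the flagged fraction over all tests.
    """
    if len(associations) == 0:
        return np.array([]), float("nan")
    ranked = associations.sort_values(
        ["p", "variant_id", "gene_id"], kind="mergesort"
    )
    flags = ranked["crossmappable"].astype(float).to_numpy()
    curve = np.cumsum(flags) / np.arange(1, len(flags) + 1)
    return curve, float(flags.mean())


def replication_fraction(
    discovery: pd.DataFrame,
    replication_pvalues: Mapping[Tuple[str, str], float],
    alpha: float,
) -> Dict[bool, float]:
    """Replication rate per cross-mappability flag class.

    One best variant per target gene is kept (lowest discovery p, ties by
    variant_id); its replication p-value is looked up, BH is applied over
    all looked-up tests, and each flag class reports the share with
    adjusted value <= alpha (NaN for an empty class). Pairs with no
    replication value are excluded and logged.
    """
    best = discovery.sort_values(["p", "variant_id"], kind="mergesort").groupby(
        "gene_id", sort=False
    ).head(1)
    rows = []
    for _, row in best.iterrows():
        key = (row["variant_id"], row["gene_id"])
        if key not in replication_pvalues:
            logger.warning("no replication value for %s; excluded", key)
            continue
        rows.append((bool(row["crossmappable"]), replication_pvalues[key]))
    out: Dict[bool, float] = {True: float("nan"), False: float("nan")}
    if not rows:
        return out
    flags = np.array([f for f, _ in rows])
    fdr = bh_fdr(np.array([p for _, p in rows]))
    for klass in (True, False):
        mask = flags == klass
        if mask.any():
            out[klass] = float((fdr[mask] <= alpha).mean())
    return out


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """|sample Pearson r|; requires n >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(abs(stats.pearsonr(x, y).statistic))


def sample_pairs(
    pairs: Sequence,
    weights: Optional[Sequence[float]],
    n: int,
    seed: int,
    mode: str = "weight_proportional",
) -> list:
    """Sample n distinct pairs without replacement.

    ``weight_proportional`` draws sequentially with probability
    proportional to the remaining weights (implemented by exponential
    keys, which yields the identical distribution); ``uniform`` ignores
    weights. Reproducible under a fixed seed.
    """
    pairs = list(pairs)
    if n > len(pairs):
        raise ValueError(f"cannot sample {n} from {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        idx = rng.choice(len(pairs), size=n, replace=False)
    elif mode == "weight_proportional":
        w = np.asarray(weights, dtype=float)
        if len(w) != len(pairs):
            raise ValueError("weights and pairs differ in length")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 and not all zero")
        keys = np.full(len(pairs), np.inf)
        positive = w > 0
        keys[positive] = rng.standard_exponential(positive.sum()) / w[positive]
        if n > positive.sum():
            raise ValueError("fewer positive-weight pairs than requested")
        idx = np.argsort(keys, kind="stable")[:n]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [pairs[i] for i in idx]


def rank_sum_greater(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p for H1: sample_a stochastically greater.

    Exact enumeration for combined n <= 20 without ties; tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)


def quantile_group_pairs(
    pairs: pd.DataFrame,
    group_spec: Sequence[int],
    weight_col: str = "crossmap_weight",
) -> pd.DataFrame:
    """Partition pairs into cross-mappability quantile groups.

    Group "0" holds all non-cross-mappable pairs (weight 0). Positive-
    weight pairs, sorted by decreasing weight, are cut into groups whose
    target sizes are given by ``group_spec`` from the top down; leftover
    positive pairs form a final group. Returns group label, size and
    weight bounds per group; truncates with a warning when there are
    fewer pairs than the spec asks for.
    """
    w = pairs[weight_col].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    rows = []
    zero = pairs.loc[w == 0]
    rows.append(
        dict(group="0", size=len(zero), weight_min=0.0, weight_max=0.0)
    )
    positive = pairs.loc[w > 0].sort_values(weight_col, ascending=False, kind="mergesort")
    start = 0
    for gi, target in enumerate(group_spec, start=1):
        if start >= len(positive):
            logger.warning("group spec truncated: pairs exhausted at group %d", gi)
            break
        chunk = positive.iloc[start : start + target]
        if len(chunk) < target:
            logger.warning(
                "group %d truncated to %d of %d pairs", gi, len(chunk), target
            )
        rows.append(
            dict(
                group=str(gi),
                size=len(chunk),
                weight_min=float(chunk[weight_col].min()),
                weight_max=float(chunk[weight_col].max()),
            )
        )
        start += len(chunk)
    if start < len(positive):
        chunk = positive.iloc[start:]
        rows.append(
            dict(
                group=str(len(group_spec) + 1),
                size=len(chunk),
                weight_min=float(chunk[weight_col].min()),
                weight_max=float(chunk[weight_col].max()),
            )
        )
    return pd.DataFrame(rows)
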