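"""Gene-level enrichment/depletion tests for FACS-sorted CRISPRi screens.

The analysis chain mirrors the standard pooled-screen workflow: median-ratio
normalization of the count matrix, per-sgRNA log2 fold changes with a
two-sided negative-binomial test in its exact conditional (beta-binomial)
form with a single dispersion pooled from the non-targeting controls, the
gene phenotype as the median LFC of a gene's sgRNAs, and a robust rank
aggregation (alpha-RRA) score per gene with a permutation p-value and
Benjamini-Hochberg FDR.

alpha-RRA: sgRNAs are ranked in the chosen direction and converted to
percentiles r in (0, 1].  For a gene with k sgRNAs and sorted percentiles
r(1) <= ... <= r(k), only the k' sgRNAs passing the alpha screen
(r <= alpha) contribute, and

    rho = min_{j <= k'} P(Beta(j, k - j + 1) <= r(j)),

the probability that the j-th order statistic of k uniforms falls at or
below r(j).  Genes with k' = 0 get rho = 1.  The permutation null reassigns
sgRNA percentiles to gene-sized groups (stratified by gene size);
p = (1 + #{perm rho <= obs rho}) / (1 + n_perm), or the exact enumeration
fraction when ``exact=True`` and the universe is small.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import NONTARGETING

__all__ = [
    "median_normalize",
    "sgrna_stats",
    "gene_phenotype",
    "alpha_rra",
    "screen_qc",
    "run_screen",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def median_normalize(counts: pd.DataFrame, sample_cols: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization across samples.

    The size factor of a sample is the median, over sgRNAs with a positive
    geometric mean across samples, of count / geometric mean; size factors
    are rescaled to geometric mean 1 (which makes the operation idempotent)
    and normalized counts are count / size factor.  All-zero sgRNA rows are
    dropped with a logged tally.

    Returns the normalized matrix (same non-count columns) and the size
    factors.
    """
    if sample_cols is None:
        sample_cols = [c for c in counts.columns if c not in ("sgrna", "gene")]
    if len(sample_cols) < 2:
        raise ValueError("median normalization needs at least 2 samples")
    mat = counts[sample_cols].to_numpy(dtype=float)
    if not (mat.sum(axis=0) > 0).all():
        raise ValueError("every sample needs at least one positive count")

    nonzero = (mat > 0).all(axis=1)
    all_zero = int((mat.sum(axis=1) == 0).sum())
    if all_zero:
        log.info("median_normalize: dropping %d all-zero sgRNA rows", all_zero)
    if not nonzero.any():
        raise ValueError("no sgRNA has positive counts in every sample")

    log_geomean = np.log(mat[nonzero]).mean(axis=1)
    ratios = np.log(mat[nonzero]) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.log(sf).mean())          # geometric mean 1

    out = counts.loc[mat.sum(axis=1) > 0].copy()
    out[sample_cols] = out[sample_cols].to_numpy(dtype=float) / sf
    return out, pd.Series(sf, index=sample_cols, name="size_factor")


# ---------------------------------------------------------------------------
# sgRNA-level statistics
# ---------------------------------------------------------------------------

_MIN_DISPERSION = 1e-7    # below this the beta-binomial is numerically binomial


def _conditional_two_sided_p(t: np.ndarray, total: np.ndarray,
                             n_t: int, n_c: int,
                             dispersion: float) -> np.ndarray:
    """Two-sided mid-p of the treatment count given the treatment+control total.

    If each replicate count is NB(m, dispersion) with a shared per-sgRNA
    mean m, the treatment sum given the total is exactly
    BetaBinomial(total, n_t/dispersion, n_c/dispersion) -- the unknown mean
    cancels, so only the pooled dispersion enters.  The dispersion -> 0
    limit is Binomial(total, n_t/(n_t+n_c)), the classical exact two-sample
    Poisson comparison.  Doubles the smaller of the two mid-p tails (the
    standard correction for discrete tests).
    """
    t = np.asarray(t)
    total = np.asarray(total)
    if dispersion < _MIN_DISPERSION:
        w = n_t / (n_t + n_c)
        half = 0.5 * stats.binom.pmf(t, total, w)
        lower = stats.binom.cdf(t, total, w) - half
        upper = stats.binom.sf(t - 1, total, w) - half
    else:
        r = 1.0 / dispersion
        half = 0.5 * stats.betabinom.pmf(t, total, n_t * r, n_c * r)
        lower = stats.betabinom.cdf(t, total, n_t * r, n_c * r) - half
        upper = stats.betabinom.sf(t - 1, total, n_t * r, n_c * r) - half
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _fit_dispersion(t: np.ndarray, total: np.ndarray,
                    n_t: int, n_c: int) -> float:
    """Pooled per-replicate NB dispersion by conditional maximum likelihood."""
    def nll(log_r: float) -> float:
        r = math.exp(log_r)
        return -stats.betabinom.logpmf(t, total, n_t * r, n_c * r).sum()

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(nll, bounds=(0.0, math.log(1.0 / _MIN_DISPERSION)),
                          method="bounded")
    alpha = math.exp(-res.x)
    # prefer the exact Poisson limit when the fit runs into the bound
    return 0.0 if alpha <= _MIN_DISPERSION * 1.01 else alpha


def sgrna_stats(norm: pd.DataFrame, treat_cols: list[str], ctrl_cols: list[str],
                pseudocount: float = 0.5, dispersion: float | None = None,
                nontargeting_label: str = NONTARGETING) -> pd.DataFrame:
    """Per-sgRNA LFC and two-sided NB p-value, treatment vs control.

    LFC is ``log2((treat + pc) / (ctrl + pc))`` on normalized counts,
    averaged over replicate pairs.  The test is the exact conditional form
    of the pooled-dispersion negative binomial model: given the
    treatment+control total, the treatment sum is beta-binomial with the
    unknown sgRNA abundance cancelled (see
    :func:`_conditional_two_sided_p`), so only the pooled per-replicate
    dispersion enters.  That dispersion is fitted by conditional maximum
    likelihood on the non-targeting sgRNAs (fallback: all sgRNAs, with a
    warning) unless passed explicitly; ``dispersion=0`` gives the exact
    two-sample Poisson comparison.  sgRNAs with a zero count in any
    compared sample are removed before testing.

    Returns a frame with ``lfc``, ``p``, ``fdr`` plus the input id columns;
    the pooled dispersion and removal tally are stored in ``.attrs``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not treat_cols or not ctrl_cols:
        raise ValueError("both treatment and control columns are required")

    treat = norm[treat_cols].to_numpy(dtype=float)
    ctrl = norm[ctrl_cols].to_numpy(dtype=float)
    keep = (treat > 0).all(axis=1) & (ctrl > 0).all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("sgrna_stats: removed %d sgRNAs with zero counts", n_removed)
    out = norm.loc[keep, [c for c in ("sgrna", "gene") if c in norm.columns]].copy()
    treat, ctrl = treat[keep], ctrl[keep]

    n_t, n_c = len(treat_cols), len(ctrl_cols)
    lfc_reps = np.log2(treat + pseudocount).mean(axis=1) \
        - np.log2(ctrl + pseudocount).mean(axis=1)

    t_sum = np.round(treat.sum(axis=1)).astype(np.int64)
    total = t_sum + np.round(ctrl.sum(axis=1)).astype(np.int64)

    if dispersion is None:
        is_nt = (out["gene"] == nontargeting_label).to_numpy() \
            if "gene" in out.columns else np.zeros(len(out), bool)
        if is_nt.sum() < 10:
            log.warning("sgrna_stats: <10 non-targeting sgRNAs; "
                        "pooling dispersion from all sgRNAs")
            is_nt = np.ones(len(out), bool)
        dispersion = _fit_dispersion(t_sum[is_nt], total[is_nt], n_t, n_c)
    out.attrs["dispersion"] = dispersion
    out.attrs["n_removed"] = n_removed

    out["lfc"] = lfc_reps
    out["p"] = _conditional_two_sided_p(t_sum, total, n_t, n_c, dispersion)
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    return out.reset_index(drop=True)


def gene_phenotype(stats_df: pd.DataFrame,
                   nontargeting_label: str = NONTARGETING) -> pd.Series:
    """Gene phenotype: the median LFC of each gene's surviving sgRNAs."""
    targeted = stats_df[stats_df["gene"] != nontargeting_label]
    if targeted.empty:
        raise ValueError("no targeted genes with surviving sgRNAs")
    return targeted.groupby("gene")["lfc"].median().rename("phenotype")


# ---------------------------------------------------------------------------
# alpha-RRA
# ---------------------------------------------------------------------------

def _rho_scores(perc: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise rho for a (m, k) matrix of percentiles."""
    k = perc.shape[1]
    r = np.sort(perc, axis=1)
    j = np.arange(1, k + 1)
    beta = stats.beta.cdf(r, j, k - j + 1)
    passing = r <= alpha
    beta = np.where(passing, beta, np.inf)      # only the alpha-screened prefix
    rho = beta.min(axis=1)
    rho[~passing.any(axis=1)] = 1.0
    return np.minimum(rho, 1.0)


def alpha_rra(lfc: pd.Series, genes: pd.Series, alpha: float = 0.25,
              n_perm: int = 2000, seed: int = 0, direction: str = "depletion",
              exact: bool = False, max_exact: int = 200_000,
              nontargeting_label: str = NONTARGETING) -> pd.DataFrame:
    """One-sided alpha-RRA gene scores with permutation p-values.

    ``lfc`` and ``genes`` are aligned per-sgRNA vectors; non-targeting
    sgRNAs contribute to the rank universe but are not scored as genes.
    ``direction="depletion"`` ranks ascending (most depleted first),
    ``"enrichment"`` descending.  Ties get average ranks.

    With ``exact=True`` and C(n, k) <= ``max_exact`` for every gene size k,
    the permutation null is enumerated exhaustively and
    p = #{subsets with rho <= obs} / #subsets.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if direction not in ("depletion", "enrichment"):
        raise ValueError("direction must be 'depletion' or 'enrichment'")
    lfc = np.asarray(lfc, dtype=float)
    genes = np.asarray(genes)
    n = len(lfc)
    key = lfc if direction == "depletion" else -lfc
    perc = stats.rankdata(key, method="average") / n

    gene_names = sorted(g for g in pd.unique(genes) if g != nontargeting_label)
    by_gene = {g: perc[genes == g] for g in gene_names}
    sizes = sorted({len(v) for v in by_gene.values()})
    pool = np.sort(perc)          # row-order invariant permutation pool

    obs_rho = {g: float(_rho_scores(v[None, :], alpha)[0]) for g, v in by_gene.items()}

    rng = np.random.default_rng(seed)
    p_vals: dict[str, float] = {}
    for k in sizes:
        members = [g for g in gene_names if len(by_gene[g]) == k]
        obs = np.array([obs_rho[g] for g in members])
        if exact and math.comb(n, k) <= max_exact:
            null = _rho_scores(
                np.array(list(itertools.combinations(pool, k))), alpha)
            counts = (null[None, :] <= obs[:, None] + 1e-12).sum(axis=1)
            ps = counts / null.size
        else:
            if n_perm < 1:
                raise ValueError("n_perm must be >= 1")
            draws = np.empty((n_perm, k))
            for i in range(n_perm):
                draws[i] = rng.choice(pool, size=k, replace=False)
            null = _rho_scores(draws, alpha)
            counts = (null[None, :] <= obs[:, None] + 1e-12).sum(axis=1)
            ps = (1.0 + counts) / (1.0 + n_perm)
        for g, p in zip(members, ps):
            p_vals[g] = float(p)

    if all(len([r for r in by_gene[g] if r <= alpha]) == 0 for g in gene_names):
        log.warning("alpha_rra: no gene has any sgRNA passing the alpha screen; "
                    "all p-values are 1")

    out = pd.DataFrame({
        "gene": gene_names,
        "n_sgrnas": [len(by_gene[g]) for g in gene_names],
        "rho": [obs_rho[g] for g in gene_names],
        "p": [p_vals[g] for g in gene_names],
    })
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    return out


# ---------------------------------------------------------------------------
# QC and the assembled analysis
# ---------------------------------------------------------------------------

@dataclass
class ScreenQC:
    essential_median_lfc: float
    nontargeting_median_lfc: float
    replicate_pearson_r: float
    replicate_r_ok: bool          # flags r < 0.7


def screen_qc(stats_df: pd.DataFrame, essential_genes: set[str],
              lfc_rep1: np.ndarray | pd.Series,
              lfc_rep2: np.ndarray | pd.Series,
              r_threshold: float = 0.7,
              nontargeting_label: str = NONTARGETING) -> ScreenQC:
    """Screen quality control: essential-gene dropout and replicate agreement.

    ``stats_df`` should hold day-13 vs day-0 LFCs; ``lfc_rep1/2`` are
    per-sgRNA LFC vectors from the two replicates of the primary contrast.
    """
    ess = stats_df.loc[stats_df["gene"].isin(essential_genes), "lfc"]
    nt = stats_df.loc[stats_df["gene"] == nontargeting_label, "lfc"]
    r = float(stats.pearsonr(np.asarray(lfc_rep1, dtype=float),
                             np.asarray(lfc_rep2, dtype=float)).statistic)
    return ScreenQC(
        essential_median_lfc=float(ess.median()) if len(ess) else float("nan"),
        nontargeting_median_lfc=float(nt.median()) if len(nt) else float("nan"),
        replicate_pearson_r=r,
        replicate_r_ok=r >= r_threshold,
    )


def run_screen(counts: pd.DataFrame, treat_cols: list[str], ctrl_cols: list[str],
               alpha: float = 0.25, n_perm: int = 2000, seed: int = 0,
               pseudocount: float = 0.5,
               nontargeting_label: str = NONTARGETING) -> pd.DataFrame:
    """Full screen test: normalize, sgRNA stats, phenotype, both RRA sides.

    Returns one row per gene with ``phenotype`` (median LFC), depletion and
    enrichment ``rho``/``p``/``fdr``, and the number of sgRNAs used.
    """
    norm, _ = median_normalize(counts, treat_cols + ctrl_cols)
    st = sgrna_stats(norm, treat_cols, ctrl_cols, pseudocount=pseudocount,
                     nontargeting_label=nontargeting_label)
    pheno = gene_phenotype(st, nontargeting_label)
    dep = alpha_rra(st["lfc"], st["gene"], alpha=alpha, n_perm=n_perm,
                    seed=seed, direction="depletion",
                    nontargeting_label=nontargeting_label)
    enr = alpha_rra(st["lfc"], st["gene"], alpha=alpha, n_perm=n_perm,
                    seed=seed + 1, direction="enrichment",
                    nontargeting_label=nontargeting_label)
    out = dep.rename(columns={"rho": "rho_depleted", "p": "p_depleted",
                              "fdr": "fdr_depleted"})
    out = out.merge(
        enr.rename(columns={"rho": "rho_enriched", "p": "p_enriched",
                            "fdr": "fdr_enriched"}).drop(columns="n_sgrnas"),
        on="gene")
    out.insert(1, "phenotype", out["gene"].map(pheno))
    return out
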