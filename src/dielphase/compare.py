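"""Between-strain transcriptome comparisons.

Three related analyses:

* fold-change calls per gene (log2 fold change with a replicate-based
  moderated t-test and Benjamini-Hochberg adjustment, called up/down at
  |FC| >= 1.5 and adjusted p < 1e-8);
* repression-fold profiles, r_g = log10((TPM_ref + c) / (TPM_test + c)) on
  replicate-mean TPMs, used to compare a strain against a clock-mutant
  reference such as an rpaA deletion;
* Pearson similarity between two profiles or two comparisons, and top-k
  most-repressed reporting with a fold-threshold cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import squeeze_variances
from .errors import InvalidInputError

FC_THRESHOLD = 1.5
PADJ_THRESHOLD = 1e-8


def _as_frame(m) -> pd.DataFrame:
    """Accept a DielMatrix or a plain genes x samples TPM DataFrame."""
    if hasattr(m, "tpm"):
        df = m.tpm.copy()
        df.columns = [f"{a}:{b}" for a, b in df.columns]
        return df
    return m


def _aligned(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(a.index) != set(b.index):
        raise InvalidInputError("gene universes of the two matrices differ")
    return a, b.loc[a.index]


@dataclass
class ExpressionComparison:
    """Per-gene fold-change test results (columns log2fc, p, padj, call)."""

    table: pd.DataFrame
    fc_threshold: float = FC_THRESHOLD
    padj_threshold: float = PADJ_THRESHOLD

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class RepressionProfile:
    """Per-gene log10 repression fold of a mutant relative to the reference."""

    values: pd.Series          # index gene_id, r_g = log10((ref+c)/(test+c))
    pseudocount: float = 1.0
    gene_filter: str = "all genes"

    def to_tsv(self, path) -> None:
        out = self.values.rename("repression_log10").to_frame()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class CorrelationResult:
    pearson_r: float
    n_genes: int
    gene_filter: str = "intersection"


@dataclass
class TopRepressedReport:
    """The k most-repressed genes plus a fold cross-check in a second profile."""

    table: pd.DataFrame        # gene_id index; repression_log10, check_log10, passes
    fold_threshold: float
    all_pass: bool


def log2fc_test(
    m_test,
    m_ref,
    pseudocount: float = 1.0,
    fc_threshold: float = FC_THRESHOLD,
    padj_threshold: float = PADJ_THRESHOLD,
) -> ExpressionComparison:
    """Per-gene log2 fold change (test vs reference) with moderated t-test.

    Works on log2(TPM + pseudocount). The per-gene pooled two-sample variance
    is squeezed toward an empirical-Bayes prior fitted across genes before
    forming the t statistic (df = pooled df + prior df), mirroring how
    count-model DE tools share dispersion information across genes; with only
    2-3 replicates an unmoderated test cannot reach the stringent adjusted-p
    cutoff at any effect size. BH adjustment across genes; a gene is called
    up/down when |fold change| >= ``fc_threshold`` and adjusted p <
    ``padj_threshold``.
    """
    a = _as_frame(m_test)
    b = _as_frame(m_ref)
    a, b = _aligned(a, b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InvalidInputError("need at least 2 replicates per side")
    xa = np.log2(a.to_numpy(float) + pseudocount)
    xb = np.log2(b.to_numpy(float) + pseudocount)
    na, nb = xa.shape[1], xb.shape[1]
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    ssq = xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)
    df_pool = na + nb - 2
    s2 = ssq / df_pool
    s2_post, d0, _ = squeeze_variances(s2, df_pool)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    df_total = df_pool + d0
    if not np.isfinite(df_total) or df_total > 1e6:
        df_total = 1e6  # effectively normal
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc / se
    p = np.empty_like(lfc)
    zero_se = ~np.isfinite(tstat)
    p[~zero_se] = 2.0 * stats.t.sf(np.abs(tstat[~zero_se]), df_total)
    # zero residual variance everywhere: identical values => no evidence
    p[zero_se] = np.where(lfc[zero_se] == 0.0, 1.0, 0.0)
    padj = multipletests(p, method="fdr_bh")[1]
    lfc_cut = np.log2(fc_threshold)
    call = np.where(
        (padj < padj_threshold) & (lfc >= lfc_cut),
        "up",
        np.where((padj < padj_threshold) & (lfc <= -lfc_cut), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": lfc, "p": p, "padj": padj, "call": call}, index=a.index
    )
    return ExpressionComparison(table=table, fc_threshold=fc_threshold, padj_threshold=padj_threshold)


def repression_profile(
    m_ref,
    m_test,
    pseudocount: float = 1.0,
    floor: float = 1.0,
) -> RepressionProfile:
    """Repression fold r_g = log10((mean TPM_ref + c)/(mean TPM_test + c)).

    Genes whose reference replicate-mean TPM falls below ``floor`` are dropped
    (lowly expressed genes make the ratio meaningless).
    """
    a = _as_frame(m_ref)
    b = _as_frame(m_test)
    a, b = _aligned(a, b)
    ref_mean = a.mean(axis=1)
    test_mean = b.mean(axis=1)
    keep = ref_mean >= floor
    r = np.log10((ref_mean[keep] + pseudocount) / (test_mean[keep] + pseudocount))
    return RepressionProfile(
        values=r,
        pseudocount=pseudocount,
        gene_filter=f"reference mean TPM >= {floor}",
    )


def correlate_profiles(p1: RepressionProfile, p2: RepressionProfile) -> CorrelationResult:
    """Pearson correlation of two repression profiles over shared genes."""
    shared = p1.values.index.intersection(p2.values.index)
    if len(shared) < 3:
        raise InvalidInputError("need at least 3 shared genes to correlate")
    r, _ = stats.pearsonr(p1.values.loc[shared], p2.values.loc[shared])
    return CorrelationResult(pearson_r=float(r), n_genes=len(shared))


def fc_correlation(c1: ExpressionComparison, c2: ExpressionComparison) -> CorrelationResult:
    """Pearson correlation between the log2 fold-change vectors of two comparisons."""
    shared = c1.table.index.intersection(c2.table.index)
    if len(shared) < 3:
        raise InvalidInputError("need at least 3 shared genes to correlate")
    r, _ = stats.pearsonr(
        c1.table.loc[shared, "log2fc"], c2.table.loc[shared, "log2fc"]
    )
    return CorrelationResult(pearson_r=float(r), n_genes=len(shared))


def top_repressed(
    p: RepressionProfile,
    k: int = 20,
    check_ref: RepressionProfile | None = None,
    fold_threshold: float = 5.0,
) -> TopRepressedReport:
    """The k genes with the largest repression fold, with a cross-check.

    Genes are ranked by descending r_g (ties broken by ascending gene id).
    When ``check_ref`` is given, each top gene is tested for linear-scale
    repression >= ``fold_threshold`` in that profile, i.e.
    r_g(check) >= log10(fold_threshold); ``all_pass`` reports whether every
    top gene passes.
    """
    if k > len(p.values):
        raise InvalidInputError(f"k={k} exceeds the {len(p.values)} genes in the profile")
    ranked = p.values.to_frame("repression_log10")
    # descending r_g; ties resolved by ascending gene id
    order = np.lexsort((ranked.index.to_numpy(), -ranked["repression_log10"].to_numpy()))
    ranked = ranked.iloc[order]
    top = ranked.head(k).copy()
    if check_ref is not None:
        cut = np.log10(fold_threshold)
        chk = check_ref.values.reindex(top.index)
        top["check_log10"] = chk
        top["passes"] = (chk >= cut).fillna(False)
        all_pass = bool(top["passes"].all())
    else:
        all_pass = True
    return TopRepressedReport(table=top, fold_threshold=fold_threshold, all_pass=all_pass)
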