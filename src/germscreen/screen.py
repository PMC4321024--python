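"""The germline-specificity screen.

Candidate previtellogenic germline-specific genes are isolated in stages:

1. Four replicate-free exact-test contrasts of the 1- to 2-day-old ovary
   against larvae, pupae, adult males, and the 24-hr PBM carcass; genes with
   BH-FDR <= alpha and higher ovary relative abundance in *all four*
   contrasts form the strict (alpha = 0.001) and relaxed (alpha = 0.01) sets.
2. An RPKM fold filter: the ratio of ovary RPKM to the mean RPKM of the four
   off-target samples, with zero RPKM values substituted (not offset) by a
   pseudocount of 0.1; genes with ratio > 100 pass.
3. Embryo-deposition refinements.  A gene expressed in the somatic follicle
   cells of the ovary leaves no transcript in the freshly laid egg, so an
   ovary-specific gene with essentially no 0-1 hr embryo signal is flagged
   as follicle-cell and removed from the final germline call.  A rise
   between consecutive embryo samples, against the expected decay of a
   maternally deposited transcript, flags (but does not remove) zygotic
   transcription.
4. A blood-meal response class (up/down/same) comparing previtellogenic and
   24-hr PBM ovaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import (
    CANONICAL_ROLE_ORDER,
    CONTRAST_ROLES,
    EMBRYO_ROLES,
    ConfigError,
    CountMatrix,
    DataError,
    ExpressionMatrix,
    SampleRole,
    ScreenConfig,
)
from .exact_test import ContrastResult, run_contrast
from .normalization import rpkm as rpkm_normalize

logger = logging.getLogger("germscreen")

__all__ = [
    "intersect_contrasts",
    "ovary_ratio",
    "follicle_cell_flag",
    "zygotic_flag",
    "bloodmeal_class",
    "mean_profile",
    "max_offtarget_rpkm",
    "run_screen",
    "ratio_refinement_table",
]


def intersect_contrasts(
    results: list[ContrastResult],
    alpha: float,
    require_ovary_up: bool = True,
) -> pd.Index:
    """Genes at FDR <= alpha in every contrast (ovary-up by default).

    The direction requirement reflects that a tissue-specific screen wants
    ovary *enrichment*; disable it to keep any differential gene.
    """
    if not results:
        raise ConfigError("no contrasts given")
    universe = results[0].gene_ids
    for res in results[1:]:
        if not universe.equals(res.gene_ids):
            raise ConfigError("contrasts cover different gene universes")
    mask = np.ones(len(universe), dtype=bool)
    for res in results:
        ok = res.table["fdr"].to_numpy() <= alpha
        if require_ovary_up:
            ok &= res.table["logfc"].to_numpy() > 0
        mask &= ok
    return universe[mask]


def _substitute_zeros(values: np.ndarray, pseudocount: float) -> np.ndarray:
    out = values.astype(float).copy()
    out[out == 0.0] = pseudocount
    return out


def ovary_ratio(expr: ExpressionMatrix, cfg: ScreenConfig) -> pd.Series:
    """Per-gene ratio of previtellogenic-ovary RPKM to the mean RPKM of the
    four off-target samples, zeros substituted by the pseudocount."""
    expr.require_roles([SampleRole.ovary_1_2, *CONTRAST_ROLES])
    ov = _substitute_zeros(expr.column(SampleRole.ovary_1_2).to_numpy(), cfg.pseudocount)
    others = np.column_stack(
        [_substitute_zeros(expr.column(r).to_numpy(), cfg.pseudocount) for r in CONTRAST_ROLES]
    )
    ratio = ov / others.mean(axis=1)
    return pd.Series(ratio, index=expr.gene_ids, name="ovary_ratio")


def max_offtarget_rpkm(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene maximum RPKM across the four off-target contrast samples."""
    expr.require_roles(CONTRAST_ROLES)
    vals = np.column_stack([expr.column(r).to_numpy() for r in CONTRAST_ROLES])
    return pd.Series(vals.max(axis=1), index=expr.gene_ids, name="max_offtarget_rpkm")


def follicle_cell_flag(expr: ExpressionMatrix, cfg: ScreenConfig) -> pd.Series:
    """True where the 0-1 hr embryo RPKM is below ``embryo_min_rpkm``
    (strict <): ovary expression without maternal deposition, the signature
    of somatic follicle-cell expression."""
    expr.require_roles([SampleRole.embryo_0_1])
    e0 = expr.column(SampleRole.embryo_0_1).to_numpy()
    return pd.Series(e0 < cfg.embryo_min_rpkm, index=expr.gene_ids, name="follicle_flag")


def zygotic_flag(expr: ExpressionMatrix, cfg: ScreenConfig) -> pd.DataFrame:
    """Flag genes whose embryo profile rises instead of decaying.

    A maternally deposited transcript should only decay across the four
    embryo windows; RPKM at any point exceeding ``zygotic_fold`` times the
    immediately preceding point (zero predecessors substituted by the
    pseudocount) indicates zygotic transcription.  Returns a DataFrame with
    a boolean ``zygotic_flag`` and the first implicated interval (e.g.
    ``"embryo_0_1:embryo_2_4"``) or None.
    """
    expr.require_roles(EMBRYO_ROLES)
    profile = np.column_stack([expr.column(r).to_numpy() for r in EMBRYO_ROLES])
    flags = np.zeros(len(profile), dtype=bool)
    intervals = np.full(len(profile), None, dtype=object)
    for k in range(1, len(EMBRYO_ROLES)):
        prev = _substitute_zeros(profile[:, k - 1], cfg.pseudocount)
        rises = (profile[:, k] > cfg.zygotic_fold * prev) & ~flags
        flags |= rises
        label = f"{EMBRYO_ROLES[k - 1].value}:{EMBRYO_ROLES[k].value}"
        intervals[rises] = label
    return pd.DataFrame(
        {"zygotic_flag": flags, "zygotic_interval": intervals}, index=expr.gene_ids
    )


def bloodmeal_class(expr: ExpressionMatrix, cfg: ScreenConfig) -> pd.Series:
    """Classify the blood-meal response of each gene as up/down/same from the
    24-hr PBM vs. previtellogenic ovary RPKM ratio (zeros substituted)."""
    expr.require_roles([SampleRole.ovary_1_2, SampleRole.ovary_24pbm])
    pre = _substitute_zeros(expr.column(SampleRole.ovary_1_2).to_numpy(), cfg.pseudocount)
    pbm = _substitute_zeros(expr.column(SampleRole.ovary_24pbm).to_numpy(), cfg.pseudocount)
    fold = pbm / pre
    cls = np.where(fold > cfg.bloodmeal_fold, "up",
                   np.where(fold < 1.0 / cfg.bloodmeal_fold, "down", "same"))
    return pd.Series(cls, index=expr.gene_ids, name="bloodmeal_class")


def mean_profile(expr: ExpressionMatrix, genes) -> pd.Series:
    """Mean RPKM per sample over a gene set, in canonical role order."""
    genes = pd.Index(genes)
    if genes.empty:
        raise DataError("mean_profile of an empty gene set")
    missing = genes.difference(expr.gene_ids)
    if len(missing):
        raise DataError(f"genes absent from the expression matrix: {list(missing[:5])}")
    order = [r for r in CANONICAL_ROLE_ORDER if expr.has_role(r)]
    values = {r.value: expr.column(r).loc[genes].mean() for r in order}
    return pd.Series(values, name="mean_rpkm")


def ratio_refinement_table(expr: ExpressionMatrix, cfg: ScreenConfig) -> pd.DataFrame:
    """The RPKM-only stages of the screen (ratio filter + refinement flags),
    usable when only a normalized expression matrix is available."""
    ratio = ovary_ratio(expr, cfg)
    table = pd.DataFrame(index=expr.gene_ids)
    table["ovary_ratio"] = ratio
    table["passes_ratio"] = ratio > cfg.fold_threshold
    table["max_offtarget_rpkm"] = max_offtarget_rpkm(expr)
    if expr.has_role(SampleRole.embryo_0_1):
        table["follicle_flag"] = follicle_cell_flag(expr, cfg)
    if all(expr.has_role(r) for r in EMBRYO_ROLES):
        zyg = zygotic_flag(expr, cfg)
        table["zygotic_flag"] = zyg["zygotic_flag"]
        table["zygotic_interval"] = zyg["zygotic_interval"]
    if expr.has_role(SampleRole.ovary_24pbm) and expr.has_role(SampleRole.ovary_1_2):
        table["bloodmeal_class"] = bloodmeal_class(expr, cfg)
    return table


def run_screen(
    counts: CountMatrix,
    lengths: pd.Series,
    cfg: ScreenConfig,
    use_tmm: bool = False,
) -> tuple[pd.DataFrame, dict, list[ContrastResult]]:
    """Run the full screen: normalization, four contrasts, intersection at
    both FDR levels, ratio filter, refinement flags, and the final call.

    Returns ``(per_gene_table, summary, contrast_results)``.  The final
    germline call is membership in the strict-FDR ovary-up intersection
    minus follicle-cell-flagged genes; zygotic-flagged genes are annotated
    but retained.
    """
    counts.require_roles([SampleRole.ovary_1_2, *CONTRAST_ROLES, SampleRole.embryo_0_1])
    expr = rpkm_normalize(counts, lengths)

    contrasts = [
        run_contrast(counts, SampleRole.ovary_1_2, other, cfg, use_tmm=use_tmm)
        for other in CONTRAST_ROLES
    ]
    strict = intersect_contrasts(contrasts, cfg.fdr_strict)
    relaxed = intersect_contrasts(contrasts, cfg.fdr_relaxed)

    table = ratio_refinement_table(expr, cfg)
    table.insert(0, "in_fdr_strict", table.index.isin(strict))
    table.insert(1, "in_fdr_relaxed", table.index.isin(relaxed))
    follicle = table.get("follicle_flag", pd.Series(False, index=table.index))
    table["germline_call"] = table["in_fdr_strict"] & ~follicle

    strict_max_off = table.loc[table["in_fdr_strict"], "max_offtarget_rpkm"]
    n_ratio = int(table["passes_ratio"].sum())
    summary = {
        "n_fdr_strict": int(table["in_fdr_strict"].sum()),
        "n_fdr_relaxed": int(table["in_fdr_relaxed"].sum()),
        "n_ratio_pass": n_ratio,
        "n_ratio_and_strict": int((table["passes_ratio"] & table["in_fdr_strict"]).sum()),
        "n_germline_final": int(table["germline_call"].sum()),
        "n_follicle_flagged": int(follicle[table["in_fdr_strict"]].sum()),
        "n_zygotic_flagged": int(table.loc[table["in_fdr_strict"], "zygotic_flag"].sum())
        if "zygotic_flag" in table else 0,
        "strict_frac_offtarget_below_11": float((strict_max_off < 11).mean())
        if len(strict_max_off) else float("nan"),
        "strict_frac_offtarget_below_5": float((strict_max_off < 5).mean())
        if len(strict_max_off) else float("nan"),
        "thresholds": {
            "fdr_strict": cfg.fdr_strict,
            "fdr_relaxed": cfg.fdr_relaxed,
            "bcv": cfg.bcv,
            "pseudocount": cfg.pseudocount,
            "fold_threshold": cfg.fold_threshold,
            "embryo_min_rpkm": cfg.embryo_min_rpkm,
            "zygotic_fold": cfg.zygotic_fold,
            "bloodmeal_fold": cfg.bloodmeal_fold,
            "tmm": use_tmm,
        },
    }
    logger.info(
        "screen: strict=%d relaxed=%d ratio>%g=%d ratio&strict=%d final=%d",
        summary["n_fdr_strict"], summary["n_fdr_relaxed"], cfg.fold_threshold,
        summary["n_ratio_pass"], summary["n_ratio_and_strict"], summary["n_germline_final"],
    )
    return table, summary, contrasts
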