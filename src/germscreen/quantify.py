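"""Droplet digital PCR and delta-delta-Ct quantification of knockdown.

ddPCR partitions a reaction into ~15,000-20,000 droplets; the fraction of
droplets that never amplify estimates the Poisson zero class, so the mean
template copies per droplet is

    lambda = -ln(1 - positives/total_droplets)

Concentration *ratios* (target over reference assay on the same cDNA) are
formed from lambda values directly because the droplet volume cancels.
Knockdown is the percent reduction of the mean per-individual target/reference
ratio in the transgenic group relative to the non-transgenic control group,
with a two-sided Welch (unequal-variance) t-test on the per-individual
ratios.

qPCR relative quantification follows the comparative-Ct scheme:
dCt = Ct_target - Ct_reference per sample, ddCt = dCt - dCt_calibrator, and
the relative quantity is RQ = 2**(-ddCt) (the calibrator's RQ is exactly 1).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ConfigError, DataError, FormatError

__all__ = [
    "ddpcr_lambda",
    "read_wells",
    "ratios_from_wells",
    "knockdown_percent",
    "read_ct_table",
    "ddct_fold_change",
]

WELL_COLUMNS = ["sample_id", "assay", "positives", "total_droplets", "group"]
CT_COLUMNS = ["sample_id", "ct_target", "ct_reference", "is_calibrator"]


def ddpcr_lambda(positives: int, total_droplets: int) -> float:
    """Mean template copies per droplet from the Poisson zero fraction."""
    if total_droplets <= 0:
        raise ValueError("total_droplets must be positive")
    if positives < 0 or positives > total_droplets:
        raise ValueError("positives must lie in [0, total_droplets]")
    if positives == total_droplets:
        raise DataError(
            f"saturated reaction ({positives}/{total_droplets} droplets positive): "
            "lambda is unbounded, dilute and repeat"
        )
    return -math.log1p(-positives / total_droplets)


def read_wells(path: str | Path) -> pd.DataFrame:
    """Read a ddPCR wells TSV (sample_id, assay, positives, total_droplets, group)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not set(df["assay"]) <= {"target", "reference"}:
        raise FormatError(f"{path}: assay must be 'target' or 'reference'")
    if not set(df["group"]) <= {"transgenic", "nontransgenic"}:
        raise FormatError(f"{path}: group must be 'transgenic' or 'nontransgenic'")
    if (df["positives"] < 0).any() or (df["positives"] > df["total_droplets"]).any():
        raise FormatError(f"{path}: positives outside [0, total_droplets]")
    return df


def ratios_from_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-individual target/reference concentration ratios from well counts.

    Each sample must have exactly one target and one reference well; the
    ratio of the two lambda estimates is the relative target concentration
    (droplet volume cancels).
    """
    rows = []
    for (sid, group), sub in wells.groupby(["sample_id", "group"], sort=True):
        by_assay = sub.set_index("assay")
        if set(by_assay.index) != {"target", "reference"} or len(sub) != 2:
            raise FormatError(
                f"sample {sid!r}: need exactly one target and one reference well"
            )
        lam_t = ddpcr_lambda(int(by_assay.loc["target", "positives"]),
                             int(by_assay.loc["target", "total_droplets"]))
        lam_r = ddpcr_lambda(int(by_assay.loc["reference", "positives"]),
                             int(by_assay.loc["reference", "total_droplets"]))
        if lam_r == 0:
            raise DataError(f"sample {sid!r}: reference assay has zero concentration")
        rows.append({
            "sample_id": sid, "group": group, "ratio": lam_t / lam_r,
            "lambda_target": lam_t, "lambda_reference": lam_r,
        })
    return pd.DataFrame(rows)


def knockdown_percent(
    transgenic,
    control,
    method: str = "mean_of_ratios",
) -> tuple[float, float]:
    """Percent knockdown of the transgenic group versus control.

    ``method='mean_of_ratios'`` averages per-individual target/reference
    ratios within each group (the default); ``'ratio_of_means'`` divides the
    group means of a two-column (target, reference) array instead.  Returns
    ``(percent, p_value)`` with the p-value from a two-sided Welch t-test on
    the per-individual ratios.
    """
    tg = np.asarray(transgenic, dtype=float)
    ct = np.asarray(control, dtype=float)
    if tg.size == 0 or ct.size == 0:
        raise DataError("both groups must be nonempty")
    if method == "mean_of_ratios":
        tg_stat, ct_stat = tg.mean(), ct.mean()
        tg_r, ct_r = tg, ct
    elif method == "ratio_of_means":
        if tg.ndim != 2 or tg.shape[1] != 2:
            raise ValueError("ratio_of_means expects (n, 2) arrays of (target, reference)")
        tg_stat = tg[:, 0].mean() / tg[:, 1].mean()
        ct_stat = ct[:, 0].mean() / ct[:, 1].mean()
        tg_r, ct_r = tg[:, 0] / tg[:, 1], ct[:, 0] / ct[:, 1]
    else:
        raise ValueError(f"unknown method {method!r}")
    if ct_stat == 0:
        raise DataError("control group mean is zero; knockdown undefined")
    percent = 100.0 * (1.0 - tg_stat / ct_stat)
    if tg_r.size > 1 and ct_r.size > 1 and (np.std(tg_r) > 0 or np.std(ct_r) > 0):
        p_value = float(stats.ttest_ind(tg_r, ct_r, equal_var=False).pvalue)
    else:
        p_value = 1.0
    return float(percent), p_value


def knockdown_from_wells(wells: pd.DataFrame, method: str = "mean_of_ratios") -> dict:
    """Full ddPCR knockdown summary from a wells table."""
    ratios = ratios_from_wells(wells)
    tg_rows = ratios[ratios["group"] == "transgenic"]
    ct_rows = ratios[ratios["group"] == "nontransgenic"]
    tg = tg_rows["ratio"].to_numpy()
    ct = ct_rows["ratio"].to_numpy()
    if method == "ratio_of_means":
        cols = ["lambda_target", "lambda_reference"]
        percent, p_value = knockdown_percent(
            tg_rows[cols].to_numpy(), ct_rows[cols].to_numpy(), method=method
        )
    else:
        percent, p_value = knockdown_percent(tg, ct, method=method)
    return {
        "knockdown_percent": percent,
        "p_value": p_value,
        "mean_ratio_transgenic": float(tg.mean()),
        "mean_ratio_nontransgenic": float(ct.mean()),
        "n_transgenic": int(tg.size),
        "n_nontransgenic": int(ct.size),
        "method": method,
    }


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all():
        raise FormatError(f"{path}: non-finite Ct value")
    return df


def ddct_fold_change(measurements: pd.DataFrame) -> pd.Series:
    """Comparative-Ct relative quantification against the flagged calibrator.

    Exactly one row must have ``is_calibrator`` true; its RQ is exactly 1.
    """
    n_cal = int(measurements["is_calibrator"].sum())
    if n_cal != 1:
        raise ConfigError(f"need exactly one calibrator, found {n_cal}")
    dct = measurements["ct_target"] - measurements["ct_reference"]
    dct_cal = float(dct[measurements["is_calibrator"]].iloc[0])
    ddct = dct - dct_cal
    rq = np.power(2.0, -ddct)
    rq[measurements["is_calibrator"].to_numpy()] = 1.0
    return pd.Series(rq.to_numpy(), index=measurements["sample_id"], name="rq")
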