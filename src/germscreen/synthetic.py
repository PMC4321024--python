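"""Synthetic 11-sample count matrices with planted gene classes.

The generator emulates the study design every pipeline stage expects: eleven
single-library samples (four embryo windows, larvae, pupae, adult males and
females, previtellogenic ovary, 24-hr PBM ovary, PBM carcass), unequal
library sizes, and negative-binomial counts with a common dispersion.  Genes
are planted in six classes whose true mean RPKM profiles mimic the expression
archetypes the screen must separate:

germline_maternal
    High expression in both ovary samples, transcript deposited in the egg
    (0-1 hr embryo signal) and decaying geometrically across the embryo time
    course; whole females inherit a fraction of the ovary signal; only a low
    leakage RPKM in larvae/pupae/males/carcass.
follicle_cell
    Ovary-restricted like the germline class but with *no* embryo signal —
    somatic follicle-cell expression is not deposited in the egg.
maternal_zygotic
    Maternal profile plus renewed transcription from the embryo's own genome
    starting at a configurable embryo window.
zygotic_only
    No ovary or adult expression; embryo expression from the onset window on.
housekeeping
    A uniform level across all eleven samples.
silent
    Zero everywhere.

For every gene and sample the true RPKM is converted to an expected count
mu = rpkm * L * N / 1e9 and the observed count is drawn NB(mean mu,
dispersion bcv**2) via the gamma-Poisson mixture; bcv = 0 gives Poisson
draws.  A truth table records each gene's class, true per-sample RPKM, and
the analytically expected screen outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    CANONICAL_ROLE_ORDER,
    CONTRAST_ROLES,
    ConfigError,
    CountMatrix,
    EMBRYO_ROLES,
    ExpressionMatrix,
    SampleRole,
    ScreenConfig,
)
from . import screen as _screen

__all__ = [
    "GeneClassSpec",
    "default_class_specs",
    "default_library_sizes",
    "generate_dataset",
    "truth_expected_summary",
    "expected_flags",
]

CLASS_NAMES = (
    "germline_maternal",
    "follicle_cell",
    "maternal_zygotic",
    "zygotic_only",
    "housekeeping",
    "silent",
)


@dataclass(frozen=True)
class GeneClassSpec:
    """Generative parameters for one planted gene class.

    ``base_rpkm_range`` bounds the log-uniform draw of each gene's peak
    (ovary or embryo-onset) expression level; ``decay_per_embryo_step`` is
    the fraction of transcript remaining at each successive embryo window;
    ``deposit_fraction`` scales the 0-1 hr embryo level relative to the
    ovary; ``offtarget_rpkm`` is the leakage level in the four contrast
    samples; ``zygotic_onset`` names the embryo window where zygotic
    transcription (amplitude ``zygotic_gain`` x base) begins.
    """

    class_name: str
    n_genes: int
    base_rpkm_range: tuple[float, float] = (50.0, 1000.0)
    decay_per_embryo_step: float = 0.5
    deposit_fraction: float = 0.8
    offtarget_rpkm: float = 0.0
    zygotic_onset: SampleRole | None = None
    zygotic_gain: float = 1.5
    female_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ConfigError(f"unknown gene class {self.class_name!r}")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if not (0.0 < self.decay_per_embryo_step <= 1.0):
            raise ConfigError("decay_per_embryo_step must be in (0, 1]")
        if self.offtarget_rpkm < 0:
            raise ConfigError("offtarget_rpkm must be >= 0")


def default_class_specs() -> list[GeneClassSpec]:
    """The default 5,000-gene composition used throughout the test suite:
    200 germline-maternal, 20 follicle-cell, 30 maternal+zygotic, 50
    zygotic-only, 4,500 housekeeping, 200 silent."""
    return [
        GeneClassSpec("germline_maternal", 200, offtarget_rpkm=0.5),
        GeneClassSpec("follicle_cell", 20, deposit_fraction=0.0),
        GeneClassSpec(
            "maternal_zygotic", 30, offtarget_rpkm=0.5, deposit_fraction=0.5,
            zygotic_onset=SampleRole.embryo_2_4,
        ),
        GeneClassSpec(
            "zygotic_only", 50, base_rpkm_range=(20.0, 500.0),
            zygotic_onset=SampleRole.embryo_4_8,
        ),
        GeneClassSpec("housekeeping", 4500, base_rpkm_range=(5.0, 100.0)),
        GeneClassSpec("silent", 200),
    ]


def default_library_sizes() -> dict[SampleRole, int]:
    """Fixed unequal library sizes (5-20 M mapped reads per sample)."""
    sizes = [
        18_000_000, 9_500_000, 14_000_000, 7_000_000,   # embryo windows
        12_000_000, 8_000_000,                          # larvae, pupae
        16_000_000, 11_000_000,                         # male, female
        6_500_000, 19_000_000, 10_500_000,              # ov 1-2d, ov 24PBM, carcass
    ]
    return dict(zip(CANONICAL_ROLE_ORDER, sizes))


def _true_profile(spec: GeneClassSpec, base: float, bm_factor: float) -> dict[SampleRole, float]:
    """True mean RPKM per sample for one gene of a class."""
    prof = {role: 0.0 for role in CANONICAL_ROLE_ORDER}
    name = spec.class_name
    if name == "silent":
        return prof
    if name == "housekeeping":
        return {role: base for role in CANONICAL_ROLE_ORDER}
    if name == "zygotic_only":
        onset = spec.zygotic_onset or SampleRole.embryo_4_8
        started = False
        for role in EMBRYO_ROLES:
            if role == onset:
                started = True
            if started:
                prof[role] = base
        return prof
    # ovary-expressing classes
    prof[SampleRole.ovary_1_2] = base
    prof[SampleRole.ovary_24pbm] = base * bm_factor
    for role in CONTRAST_ROLES:
        prof[role] = spec.offtarget_rpkm
    prof[SampleRole.female_1_5] = spec.offtarget_rpkm + spec.female_fraction * base
    deposit = spec.deposit_fraction * base
    for k, role in enumerate(EMBRYO_ROLES):
        prof[role] = deposit * spec.decay_per_embryo_step ** k
    if name == "maternal_zygotic":
        onset = spec.zygotic_onset or SampleRole.embryo_2_4
        started = False
        for role in EMBRYO_ROLES:
            if role == onset:
                started = True
            if started:
                prof[role] += spec.zygotic_gain * base
    return prof


def generate_dataset(
    specs: list[GeneClassSpec] | None = None,
    lib_sizes: dict[SampleRole, int] | None = None,
    bcv: float = 0.4,
    seed: int = 0,
    length_range: tuple[int, int] = (500, 5000),
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Draw a synthetic dataset; returns (counts, gene lengths, truth table).

    The truth table is indexed by gene id with columns ``class_name``, one
    ``rpkm_<role>`` column of true mean RPKM per sample, and the expected
    screen flags from :func:`expected_flags`.
    """
    if specs is None:
        specs = default_class_specs()
    if lib_sizes is None:
        lib_sizes = default_library_sizes()
    missing = [r.value for r in CANONICAL_ROLE_ORDER if r not in lib_sizes]
    if missing:
        raise ConfigError(f"lib_sizes missing roles: {missing}")
    if any(n <= 0 for n in lib_sizes.values()):
        raise ConfigError("library sizes must be positive")
    if bcv < 0:
        raise ConfigError("bcv must be non-negative")

    rng = np.random.default_rng(seed)
    roles = list(CANONICAL_ROLE_ORDER)
    N = np.array([lib_sizes[r] for r in roles], dtype=float)

    gene_ids: list[str] = []
    classes: list[str] = []
    lengths: list[int] = []
    true_rpkm_rows: list[np.ndarray] = []
    for spec in specs:
        for i in range(spec.n_genes):
            gid = f"{spec.class_name}_{i:05d}"
            lo, hi = spec.base_rpkm_range
            base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            # blood-meal response factor: mixture of down / same / up
            bm_factor = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
            prof = _true_profile(spec, base, bm_factor)
            gene_ids.append(gid)
            classes.append(spec.class_name)
            lengths.append(int(rng.integers(length_range[0], length_range[1] + 1)))
            true_rpkm_rows.append(np.array([prof[r] for r in roles]))

    n_genes = len(gene_ids)
    sample_ids = [f"S_{r.value}" for r in roles]
    if n_genes == 0:
        counts_df = pd.DataFrame(
            np.zeros((0, len(roles)), dtype=np.int64),
            index=pd.Index([], name="gene_id"), columns=sample_ids,
        )
        cm = CountMatrix(counts_df, dict(zip(sample_ids, roles)))
        truth = pd.DataFrame(index=pd.Index([], name="gene_id"))
        return cm, pd.Series([], dtype=np.int64, name="length_nt"), truth

    true_rpkm = np.vstack(true_rpkm_rows)
    L = np.array(lengths, dtype=float)
    mu = true_rpkm * L[:, None] * N[None, :] / 1e9
    counts = np.zeros_like(mu, dtype=np.int64)
    positive = mu > 0
    if bcv == 0:
        counts[positive] = rng.poisson(mu[positive])
    else:
        phi = bcv * bcv
        lam = rng.gamma(shape=1.0 / phi, scale=mu[positive] * phi)
        counts[positive] = rng.poisson(lam)

    index = pd.Index(gene_ids, name="gene_id")
    counts_df = pd.DataFrame(counts, index=index, columns=sample_ids)
    cm = CountMatrix(counts_df, dict(zip(sample_ids, roles)))
    length_series = pd.Series(lengths, index=index, name="length_nt")

    truth = pd.DataFrame({"class_name": classes}, index=index)
    for j, role in enumerate(roles):
        truth[f"rpkm_{role.value}"] = true_rpkm[:, j]
    truth = truth.join(expected_flags(truth, ScreenConfig()))
    return cm, length_series, truth


def _truth_expression(truth: pd.DataFrame) -> ExpressionMatrix:
    cols = {c: SampleRole(c.removeprefix("rpkm_")) for c in truth.columns if c.startswith("rpkm_")}
    df = truth[list(cols)].copy()
    df.columns = [f"S_{r.value}" for r in cols.values()]
    return ExpressionMatrix(df, dict(zip(df.columns, cols.values())))


def expected_flags(truth: pd.DataFrame, cfg: ScreenConfig, detect_rpkm: float = 5.0,
                   margin: float = 10.0) -> pd.DataFrame:
    """Analytically expected screen outcome from *true* mean RPKM profiles.

    A gene is expected in the strict DE intersection when its true ovary
    RPKM is detectable (>= ``detect_rpkm``) and exceeds every contrast
    sample's true RPKM by at least ``margin``-fold — under the generator's
    defaults this separates classes unambiguously, so the expectation is a
    property of the class design, not of any sampled data.  The ratio,
    follicle, zygotic and blood-meal expectations reuse the screen's own
    RPKM rules on the true profiles.
    """
    expr = _truth_expression(truth)
    ov = expr.column(SampleRole.ovary_1_2).to_numpy()
    off = np.column_stack([expr.column(r).to_numpy() for r in CONTRAST_ROLES])
    expected_strict = (ov >= detect_rpkm) & np.all(
        ov[:, None] >= margin * np.maximum(off, 1e-12), axis=1
    )
    out = pd.DataFrame(index=truth.index)
    out["expected_strict"] = expected_strict
    out["expected_ratio_pass"] = _screen.ovary_ratio(expr, cfg).to_numpy() > cfg.fold_threshold
    out["expected_follicle_flag"] = _screen.follicle_cell_flag(expr, cfg).to_numpy()
    out["expected_zygotic_flag"] = _screen.zygotic_flag(expr, cfg)["zygotic_flag"].to_numpy()
    out["expected_germline"] = out["expected_strict"] & ~out["expected_follicle_flag"]
    return out


def truth_expected_summary(truth: pd.DataFrame, cfg: ScreenConfig) -> dict:
    """Expected headline counts of the screen given the planted truth."""
    flags = expected_flags(truth, cfg)
    return {
        "n_fdr_strict": int(flags["expected_strict"].sum()),
        "n_ratio_pass": int(flags["expected_ratio_pass"].sum()),
        "n_germline_final": int(flags["expected_germline"].sum()),
        "n_follicle_flagged": int(
            (flags["expected_strict"] & flags["expected_follicle_flag"]).sum()
        ),
    }
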