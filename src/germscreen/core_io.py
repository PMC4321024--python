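"""Domain types, readers/writers, sample-role resolution and configuration.

The pipeline operates on an 11-sample, one-library-per-sample RNA-seq design
covering a mosquito life course: four early embryo windows (0-1, 2-4, 4-8 and
8-12 hr), pooled larvae, pupae, 1- to 5-day-old adult males and females,
1- to 2-day-old previtellogenic ovaries, 24-hr post-blood-meal (PBM) ovaries,
and the 24-hr PBM female carcass with ovaries removed.  Samples are bound to
these biological roles through an explicit sample sheet rather than by column
naming conventions.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("germscreen")

__all__ = [
    "GermscreenError",
    "FormatError",
    "ConfigError",
    "DataError",
    "SampleRole",
    "CANONICAL_ROLE_ORDER",
    "CONTRAST_ROLES",
    "SCREEN_ROLES",
    "EMBRYO_ROLES",
    "CountMatrix",
    "ExpressionMatrix",
    "ScreenConfig",
    "read_sample_sheet",
    "read_counts",
    "read_gene_lengths",
    "read_rpkm",
    "write_rpkm",
    "write_screen_table",
    "read_screen_table",
    "read_config",
    "write_config",
]


class GermscreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GermscreenError):
    """Malformed input file (bad value, duplicate id, unknown role)."""


class ConfigError(GermscreenError):
    """Invalid configuration or missing required sample role."""


class DataError(GermscreenError):
    """Data that is structurally valid but unusable (all-zero library,
    missing gene length, degenerate group)."""


class SampleRole(str, enum.Enum):
    """Biological role of one RNA-seq library in the 11-sample design."""

    embryo_0_1 = "embryo_0_1"
    embryo_2_4 = "embryo_2_4"
    embryo_4_8 = "embryo_4_8"
    embryo_8_12 = "embryo_8_12"
    larvae = "larvae"
    pupae = "pupae"
    male_1_5 = "male_1_5"
    female_1_5 = "female_1_5"
    ovary_1_2 = "ovary_1_2"
    ovary_24pbm = "ovary_24pbm"
    carcass_24pbm = "carcass_24pbm"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Role order used for profile outputs (embryo time course first, then
#: juvenile stages, adults, and the three ovary/carcass samples).
CANONICAL_ROLE_ORDER: tuple[SampleRole, ...] = (
    SampleRole.embryo_0_1,
    SampleRole.embryo_2_4,
    SampleRole.embryo_4_8,
    SampleRole.embryo_8_12,
    SampleRole.larvae,
    SampleRole.pupae,
    SampleRole.male_1_5,
    SampleRole.female_1_5,
    SampleRole.ovary_1_2,
    SampleRole.ovary_24pbm,
    SampleRole.carcass_24pbm,
)

#: The four samples the previtellogenic ovary is contrasted against.  The
#: embryos are excluded because maternally deposited transcripts would mask
#: germline specificity; whole females are excluded because they contain the
#: ovary; the PBM ovary is excluded so genes need not be previtellogenic-only.
CONTRAST_ROLES: tuple[SampleRole, ...] = (
    SampleRole.larvae,
    SampleRole.pupae,
    SampleRole.male_1_5,
    SampleRole.carcass_24pbm,
)

#: Roles a differential-expression screen cannot run without.
SCREEN_ROLES: tuple[SampleRole, ...] = (SampleRole.ovary_1_2,) + CONTRAST_ROLES

EMBRYO_ROLES: tuple[SampleRole, ...] = (
    SampleRole.embryo_0_1,
    SampleRole.embryo_2_4,
    SampleRole.embryo_4_8,
    SampleRole.embryo_8_12,
)


def _validate_roles(roles: Mapping[str, SampleRole], sample_ids: Iterable[str]) -> dict[str, SampleRole]:
    out: dict[str, SampleRole] = {}
    seen_roles: set[SampleRole] = set()
    for sid in sample_ids:
        if sid not in roles:
            raise ConfigError(f"sample {sid!r} has no role in the sample sheet")
        role = roles[sid]
        if role in seen_roles:
            raise FormatError(f"role {role} assigned to more than one sample")
        seen_roles.add(role)
        out[sid] = role
    return out


@dataclass(frozen=True)
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample; ``roles`` maps every column to its :class:`SampleRole`.
    """

    counts: pd.DataFrame
    roles: Mapping[str, SampleRole]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(values < 0):
            raise FormatError("negative counts are not allowed")
        if not np.array_equal(values, np.floor(values)):
            raise FormatError("counts must be integers")
        object.__setattr__(self, "roles", _validate_roles(self.roles, self.counts.columns))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_for_role(self, role: SampleRole) -> str:
        for sid, r in self.roles.items():
            if r == role:
                return sid
        raise ConfigError(f"no sample with role {role} in the count matrix")

    def has_role(self, role: SampleRole) -> bool:
        return any(r == role for r in self.roles.values())

    def column(self, role: SampleRole) -> pd.Series:
        return self.counts[self.sample_for_role(role)]

    def require_roles(self, required: Iterable[SampleRole]) -> None:
        missing = [r.value for r in required if not self.has_role(r)]
        if missing:
            raise ConfigError(f"required sample roles missing: {missing}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample RPKM values with the same role binding as CountMatrix."""

    rpkm: pd.DataFrame
    roles: Mapping[str, SampleRole]

    def __post_init__(self) -> None:
        if np.any(self.rpkm.to_numpy() < 0):
            raise FormatError("RPKM values must be non-negative")
        object.__setattr__(self, "roles", _validate_roles(self.roles, self.rpkm.columns))

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index

    def sample_for_role(self, role: SampleRole) -> str:
        for sid, r in self.roles.items():
            if r == role:
                return sid
        raise ConfigError(f"no sample with role {role} in the expression matrix")

    def has_role(self, role: SampleRole) -> bool:
        return any(r == role for r in self.roles.values())

    def column(self, role: SampleRole) -> pd.Series:
        return self.rpkm[self.sample_for_role(role)]

    def require_roles(self, required: Iterable[SampleRole]) -> None:
        missing = [r.value for r in required if not self.has_role(r)]
        if missing:
            raise ConfigError(f"required sample roles missing: {missing}")


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the germline-specificity screen.

    fdr_strict / fdr_relaxed
        BH-adjusted p-value cutoffs defining the stringent and relaxed
        differentially-expressed gene sets (defaults 0.001 and 0.01).
    bcv
        Biological coefficient of variation assumed for the replicate-free
        exact test; the negative-binomial dispersion is ``bcv**2``.
    pseudocount
        Value substituted for zero RPKM entries inside ratio statistics
        (substitution, not addition).
    fold_threshold
        Ovary-to-mean-off-target RPKM ratio above which a gene passes the
        fold filter (strict ``>``).
    embryo_min_rpkm
        0-1 hr embryo RPKM below which an ovary-specific gene is flagged as
        likely somatic follicle-cell expression (no maternal deposition).
    zygotic_fold
        Fold rise between consecutive embryo samples that flags zygotic
        transcription against the expected maternal decay.
    bloodmeal_fold
        Fold change between previtellogenic and 24-hr PBM ovary classifying
        a gene as up/down/same after a blood meal.
    """

    fdr_strict: float = 0.001
    fdr_relaxed: float = 0.01
    bcv: float = 0.4
    pseudocount: float = 0.1
    fold_threshold: float = 100.0
    embryo_min_rpkm: float = 1.0
    zygotic_fold: float = 2.0
    bloodmeal_fold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_strict <= self.fdr_relaxed < 1.0):
            raise ConfigError("require 0 < fdr_strict <= fdr_relaxed < 1")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if self.fold_threshold <= 0:
            raise ConfigError("fold_threshold must be positive")
        if self.bcv < 0:
            raise ConfigError("bcv must be non-negative")
        if self.embryo_min_rpkm < 0:
            raise ConfigError("embryo_min_rpkm must be non-negative")
        if self.zygotic_fold <= 0 or self.bloodmeal_fold <= 0:
            raise ConfigError("fold parameters must be positive")

    @property
    def dispersion(self) -> float:
        """Negative-binomial dispersion phi = bcv**2."""
        return self.bcv * self.bcv

    def with_overrides(self, **kwargs) -> "ScreenConfig":
        return replace(self, **kwargs)


def read_sample_sheet(path: str | Path) -> dict[str, SampleRole]:
    """Read a two-column TSV (sample_id, role) mapping samples to roles."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" not in cols or "role" not in cols:
        raise FormatError(f"{path}: sample sheet needs 'sample_id' and 'role' columns")
    df.columns = cols
    roles: dict[str, SampleRole] = {}
    for _, row in df.iterrows():
        sid, role_name = row["sample_id"], row["role"]
        try:
            role = SampleRole(role_name)
        except ValueError:
            raise FormatError(
                f"{path}: unknown role {role_name!r} for sample {sid!r}"
            ) from None
        if sid in roles:
            raise FormatError(f"{path}: duplicate sample id {sid!r}")
        if role in roles.values():
            raise FormatError(f"{path}: role {role} assigned twice")
        roles[sid] = role
    return roles


def read_counts(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a gene x sample TSV count matrix plus its sample sheet.

    The first column holds gene ids; the header row holds sample ids which
    must all appear in the sample sheet.  Counts must be non-negative
    integers.
    """
    roles = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise FormatError(f"{path}: no sample columns")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise FormatError(f"{path}: non-numeric counts in columns {list(bad)}")
    try:
        return CountMatrix(df, roles)
    except GermscreenError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read per-gene transcript lengths (nt).

    Accepts either a two-column TSV ``gene_id<TAB>length_nt`` or a GFF3 file,
    in which case the length of each transcript is the sum of its exon
    lengths (GFF coordinates are 1-based inclusive, so an exon spans
    ``end - start + 1`` nt).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _lengths_from_gff(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene_id, length_nt)")
    # tolerate an optional header line
    first = str(df.iloc[0, 1])
    if not first.lstrip("-").isdigit():
        df = df.iloc[1:]
    genes = df.iloc[:, 0].astype(str)
    try:
        lengths = df.iloc[:, 1].astype(int)
    except ValueError:
        raise FormatError(f"{path}: non-integer length value") from None
    if (lengths <= 0).any():
        bad = genes[lengths.to_numpy() <= 0].tolist()
        raise FormatError(f"{path}: non-positive length for {bad[:5]}")
    if genes.duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in length table")
    out = pd.Series(lengths.to_numpy(), index=pd.Index(genes, name="gene_id"), name="length_nt")
    return out


def _lengths_from_gff(path: Path) -> pd.Series:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    totals: dict[str, int] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("gene_id") or []
        if not parents and exon.id:
            parents = [exon.id]
        length = exon.end - exon.start + 1
        if length <= 0:
            raise FormatError(f"{path}: exon with non-positive length at {exon.start}-{exon.end}")
        for parent in parents:
            totals[parent] = totals.get(parent, 0) + length
    if not totals:
        raise FormatError(f"{path}: no exon features found")
    return pd.Series(totals, name="length_nt").rename_axis("gene_id")


def read_rpkm(path: str | Path, sample_sheet: str | Path) -> ExpressionMatrix:
    """Read a precomputed gene x sample RPKM matrix (e.g. a published
    normalized-expression table) so downstream ratio/refinement stages can
    run without raw counts."""
    roles = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return ExpressionMatrix(df.astype(float), roles)
    except GermscreenError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_rpkm(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.rpkm.rename_axis("gene_id").to_csv(path, sep="\t")


#: Stable column order of the per-gene screen table.
SCREEN_TABLE_COLUMNS = [
    "in_fdr_strict",
    "in_fdr_relaxed",
    "ovary_ratio",
    "passes_ratio",
    "follicle_flag",
    "zygotic_flag",
    "zygotic_interval",
    "bloodmeal_class",
    "max_offtarget_rpkm",
    "germline_call",
]


def write_screen_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene screen result TSV in the documented column order."""
    cols = [c for c in SCREEN_TABLE_COLUMNS if c in result.columns]
    extra = [c for c in result.columns if c not in cols]
    result[cols + extra].rename_axis("gene_id").to_csv(path, sep="\t")


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("in_fdr_strict", "in_fdr_relaxed", "passes_ratio", "follicle_flag",
                "zygotic_flag", "germline_call"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "zygotic_interval" in df.columns:
        df["zygotic_interval"] = df["zygotic_interval"].where(df["zygotic_interval"].notna(), None)
    return df


_CONFIG_TYPES = {f.name: f.type for f in fields(ScreenConfig)}


def read_config(path: str | Path) -> ScreenConfig:
    """Read a flat ``key = value`` configuration file mirroring ScreenConfig."""
    kwargs: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_TYPES:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = int(value) if key == "seed" else float(value)
    return ScreenConfig(**kwargs)


def write_config(cfg: ScreenConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in fields(ScreenConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
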