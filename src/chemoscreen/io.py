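"""Tabular screen artifacts: count tables, sample sheets, guide libraries,
gene-score tables.

All files are tab-separated UTF-8 text; lines starting with ``#`` are
comments. Validation is total — malformed input raises
:class:`~chemoscreen.errors.ValidationError` with a diagnostic naming the
offending row/column/sample, never a silently coerced value. Writes are
byte-stable (fixed column order, stable sort) so repeated writes of the
same table are identical, and write→read round-trips are the identity.

Conventions
-----------
* Count table: header ``guide_id  gene_id  <sample...>``; one row per guide;
  counts are non-negative integers with no missing cells.
* Sample sheet: columns ``sample_id  arm  compound  bio_rep  tech_rep``;
  ``arm`` is one of T0/mock/treated; ``compound`` is empty for T0 and may be
  empty for mock (a shared vehicle/DMSO arm that matches every compound).
* Gene scores: columns ``gene_id  n_guides  effect  t  df  p  q  hit_class``.
* Control (non-targeting) guides are flagged by a gene-id prefix
  (default ``CTRL``); they pass through normalization but are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

ARMS = ("T0", "mock", "treated")
HIT_CLASSES = ("resistant", "sensitive", "none")

SAMPLE_SHEET_COLUMNS = ["sample_id", "arm", "compound", "bio_rep", "tech_rep"]
LIBRARY_COLUMNS = ["guide_id", "gene_id", "is_control"]
GENE_SCORE_COLUMNS = ["gene_id", "n_guides", "effect", "t", "df", "p", "q", "hit_class"]

DEFAULT_CONTROL_PREFIX = "CTRL"

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False, na_values=[])


@dataclass
class CountMatrix:
    """Raw integer guide × sample read counts with library/sample metadata.

    Attributes
    ----------
    library : DataFrame with columns guide_id, gene_id, is_control,
        one row per guide, in count-matrix row order.
    samples : DataFrame with the sample-sheet columns, in count-matrix
        column order. ``compound`` is None where absent.
    counts : DataFrame indexed by guide_id with one integer column per
        sample_id.
    """

    library: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        validate_library(self.library)
        validate_sample_sheet(self.samples)
        if list(self.counts.index) != list(self.library["guide_id"]):
            raise ValidationError("count-matrix row order does not match the guide library")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValidationError("count-matrix column order does not match the sample sheet")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n_guides(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def validate_library(lib: pd.DataFrame) -> None:
    missing = [c for c in LIBRARY_COLUMNS if c not in lib.columns]
    if missing:
        raise ValidationError(f"guide library is missing columns: {missing}")
    dup = lib["guide_id"][lib["guide_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate guide_id: {dup.iloc[0]!r}")
    if lib["gene_id"].isna().any() or (lib["gene_id"] == "").any():
        raise ValidationError("every guide must map to exactly one non-empty gene_id")


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet is missing columns: {missing}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")
    bad_arm = sheet.loc[~sheet["arm"].isin(ARMS), "arm"]
    if len(bad_arm):
        raise ValidationError(f"unknown arm {bad_arm.iloc[0]!r} (expected one of {ARMS})")
    if not (sheet["arm"] == "T0").any():
        raise ValidationError("sample sheet must contain at least one T0 sample")
    for col in ("bio_rep", "tech_rep"):
        vals = sheet[col]
        if vals.isna().any() or (vals.astype(int) != vals).any() or (vals.astype(int) < 1).any():
            raise ValidationError(f"{col} must be positive integers")
    treated = sheet[sheet["arm"] == "treated"]
    if treated["compound"].isna().any():
        raise ValidationError("treated samples must name a compound")
    mock = sheet[sheet["arm"] == "mock"]
    for _, row in treated.iterrows():
        match = mock[
            (mock["bio_rep"] == row["bio_rep"])
            & (mock["compound"].isna() | (mock["compound"] == row["compound"]))
        ]
        if match.empty:
            raise ValidationError(
                f"treated sample {row['sample_id']!r} (compound {row['compound']!r}, "
                f"bio_rep {row['bio_rep']}) has no matching mock sample"
            )


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, **_READ_KW)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"{path}: sample sheet is missing columns: {missing}")
    sheet = sheet[SAMPLE_SHEET_COLUMNS].copy()
    sheet["compound"] = sheet["compound"].replace("", None)
    for col in ("bio_rep", "tech_rep"):
        try:
            sheet[col] = sheet[col].astype(int)
        except ValueError as exc:
            raise ValidationError(f"{path}: column {col!r} must be integer: {exc}") from None
    validate_sample_sheet(sheet)
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    out = sheet[SAMPLE_SHEET_COLUMNS].copy()
    out["compound"] = out["compound"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_guide_library(path) -> pd.DataFrame:
    lib = pd.read_csv(path, **_READ_KW)
    missing = [c for c in LIBRARY_COLUMNS if c not in lib.columns]
    if missing:
        raise ValidationError(f"{path}: guide library is missing columns: {missing}")
    lib = lib[LIBRARY_COLUMNS].copy()
    bad = ~lib["is_control"].isin(["True", "False"])
    if bad.any():
        raise ValidationError(
            f"{path}: is_control must be True/False, got {lib.loc[bad, 'is_control'].iloc[0]!r}"
        )
    lib["is_control"] = lib["is_control"] == "True"
    validate_library(lib)
    return lib.reset_index(drop=True)


def write_guide_library(lib: pd.DataFrame, path) -> None:
    validate_library(lib)
    lib[LIBRARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_count_table(path, sample_sheet_path, control_prefix: str = DEFAULT_CONTROL_PREFIX) -> CountMatrix:
    """Read a guide count TSV plus its sample sheet into a validated CountMatrix.

    The count table header is ``guide_id  gene_id  <sample...>``; its sample
    columns must exactly cover the sample sheet, and are reordered to
    sample-sheet order. Guides whose gene_id starts with ``control_prefix``
    are flagged as non-targeting controls.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    raw = pd.read_csv(path, **_READ_KW)
    if list(raw.columns[:2]) != ["guide_id", "gene_id"]:
        raise ValidationError(f"{path}: header must start with 'guide_id\\tgene_id'")
    dup = raw["guide_id"][raw["guide_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate guide_id {dup.iloc[0]!r}")

    count_samples = list(raw.columns[2:])
    sheet_samples = list(sheet["sample_id"])
    extra = sorted(set(count_samples) - set(sheet_samples))
    if extra:
        raise ValidationError(f"{path}: sample {extra[0]!r} is missing from the sample sheet")
    absent = sorted(set(sheet_samples) - set(count_samples))
    if absent:
        raise ValidationError(f"{path}: sample {absent[0]!r} from the sample sheet has no count column")

    counts = {}
    for col in count_samples:
        try:
            vals = pd.to_numeric(raw[col], errors="raise")
        except ValueError:
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric count {bad.iloc[0]!r} for guide "
                f"{raw.loc[bad.index[0], 'guide_id']!r}, sample {col!r}"
            ) from None
        neg = vals < 0
        if neg.any():
            g = raw.loc[neg.idxmax(), "guide_id"]
            raise ValidationError(f"{path}: negative count for guide {g!r}, sample {col!r}")
        frac = vals != np.floor(vals)
        if frac.any():
            g = raw.loc[frac.idxmax(), "guide_id"]
            raise ValidationError(f"{path}: non-integer count for guide {g!r}, sample {col!r}")
        counts[col] = vals.astype(np.int64)

    count_df = pd.DataFrame(counts)[sheet_samples]
    count_df.index = pd.Index(raw["guide_id"], name="guide_id")
    library = pd.DataFrame(
        {
            "guide_id": raw["guide_id"],
            "gene_id": raw["gene_id"],
            "is_control": raw["gene_id"].str.startswith(control_prefix),
        }
    ).reset_index(drop=True)
    return CountMatrix(library=library, samples=sheet, counts=count_df)


def write_count_table(counts: CountMatrix, path) -> None:
    out = counts.counts.reset_index()
    out.insert(1, "gene_id", counts.library["gene_id"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


def _validate_gene_scores(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"gene-score table is missing columns: {missing}")
    if not np.isfinite(table["effect"].to_numpy(dtype=float)).all():
        raise ValidationError("gene-score effects must be finite")
    q = table["q"].to_numpy(dtype=float)
    if np.isnan(q).any() or (q < 0).any() or (q > 1).any():
        raise ValidationError("q values must lie in [0, 1] with no NaN")
    bad = ~table["hit_class"].isin(HIT_CLASSES)
    if bad.any():
        raise ValidationError(f"unknown hit_class {table.loc[bad, 'hit_class'].iloc[0]!r}")
    return table


def write_gene_scores(table: pd.DataFrame, path) -> None:
    """Write a gene-score table (stable sort by gene_id, fixed columns).

    Floats are written at full shortest-repr precision so that
    ``read_gene_scores(write_gene_scores(x)) == x`` exactly.
    """
    _validate_gene_scores(table)
    out = table[GENE_SCORE_COLUMNS].sort_values("gene_id", kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_gene_scores(path) -> pd.DataFrame:
    table = pd.read_csv(path, **_READ_KW)
    missing = [c for c in GENE_SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: gene-score table is missing columns: {missing}")
    table = table[GENE_SCORE_COLUMNS].copy()
    table["n_guides"] = table["n_guides"].astype(int)
    for col in ("effect", "t", "df", "p", "q"):
        try:
            # float() is correctly rounded, so write->read round-trips exactly
            table[col] = table[col].map(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric value in column {col!r}: {exc}") from None
    return _validate_gene_scores(table.reset_index(drop=True))
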