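"""Read/validate Cq tables, write result reports, and load packaged fixtures.

The only input dialect is a long (tidy) CSV with header
``gene_id,cultivar,tissue,treatment,timepoint_h,bio_replicate,cq``; one row per
well-averaged biological replicate. Treatment labels are free strings mapped
to {control, stress} through the :class:`~drqpcr.design.ExperimentDesign`.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from drqpcr.design import ExperimentDesign

if TYPE_CHECKING:  # pragma: no cover
    from drqpcr.candidate_selection import StateMatrix

CQ_COLUMNS = [
    "gene_id",
    "cultivar",
    "tissue",
    "treatment",
    "timepoint_h",
    "bio_replicate",
    "cq",
]

KEY_COLUMNS = CQ_COLUMNS[:-1]

#: Cq range of a standard 40–45 cycle qPCR run.
CQ_MIN, CQ_MAX = 0.0, 45.0


class CqTableError(ValueError):
    """Raised when a Cq table violates a structural invariant."""


class CqTable:
    """Validated tidy table of quantification-cycle measurements.

    The underlying :class:`pandas.DataFrame` is available as ``.df`` with
    treatments already normalized to {control, stress}.
    """

    def __init__(self, df: pd.DataFrame, design: ExperimentDesign):
        missing = [c for c in CQ_COLUMNS if c not in df.columns]
        if missing:
            raise CqTableError(f"missing required columns: {missing}")
        df = df[CQ_COLUMNS].copy()
        df["timepoint_h"] = df["timepoint_h"].astype(float)
        df["bio_replicate"] = df["bio_replicate"].astype(int)
        df["cq"] = df["cq"].astype(float)
        if set(df["treatment"]) - {"control", "stress"}:
            df["treatment"] = df["treatment"].map(design.map_treatment)
        self._validate(df, design)
        self.df = df.reset_index(drop=True)
        self.design = design

    @staticmethod
    def _validate(df: pd.DataFrame, design: ExperimentDesign) -> None:
        bad = df.index[(df["cq"] <= CQ_MIN) | (df["cq"] > CQ_MAX)]
        if len(bad):
            row = int(bad[0])
            raise CqTableError(
                f"cq out of range ({CQ_MIN}, {CQ_MAX}] at row {row}: "
                f"cq={df.loc[row, 'cq']}"
            )
        if (df["bio_replicate"] < 1).any():
            raise CqTableError("bio_replicate must be >= 1")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise CqTableError(f"duplicate measurement key: {first}")
        # reference gene must cover every (cultivar, tissue, treatment,
        # timepoint, replicate) cell spanned by any target gene
        cell_cols = KEY_COLUMNS[1:]
        cells = df[cell_cols].drop_duplicates()
        ref = df[df["gene_id"] == design.reference_gene][cell_cols]
        merged = cells.merge(ref, on=cell_cols, how="left", indicator=True)
        absent = merged[merged["_merge"] == "left_only"]
        if len(absent):
            cell = absent.iloc[0][cell_cols].tolist()
            raise CqTableError(
                f"reference gene {design.reference_gene!r} missing for cell "
                f"(cultivar, tissue, treatment, timepoint_h, replicate) = {cell}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def genes(self) -> list[str]:
        return sorted(self.df["gene_id"].unique())

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_cq_table(path: str | Path, design: ExperimentDesign) -> CqTable:
    """Read and validate a tidy Cq CSV.

    Raises :class:`CqTableError` on a malformed header, duplicate keys, Cq
    values outside (0, 45], or reference-gene rows missing for any design cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return CqTable(df, design)


def write_report(results: pd.DataFrame, path: str | Path) -> None:
    """Write a stage output as TSV with stable column order.

    Floats are serialized at 6 significant digits so reports are diffable
    across platforms.
    """
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _data_path(name: str):
    from importlib import resources

    return resources.files("drqpcr") / "data" / name


def load_primer_table() -> pd.DataFrame:
    """Packaged RT-qPCR primer metadata (19 targets + reference gene)."""
    with _data_path("primers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


_CELLS = [("control", 2.0), ("control", 5.0), ("stress", 2.0), ("stress", 5.0)]
_PATTERNS = {"up", "down", "mixed", "unchanged"}
_CONTRASTS = {"higher", "lower", "similar"}
_DIRS = {"up", "down", "none"}


def load_paper_call_table() -> pd.DataFrame:
    """Raw packaged call matrix: one row per gene × tissue.

    Columns hold the qualitative dehydration direction per cultivar and
    timepoint, the overall response patterns, the tolerant/sensitive contrast
    call per (treatment, timepoint) cell, and an ``ambiguous`` column naming
    cells whose value could not be pinned down from the published enumeration.
    """
    with _data_path("call_matrix.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    _check_call_table(df)
    return df


def _check_call_table(df: pd.DataFrame) -> None:
    genes = df["gene_id"].unique()
    if len(genes) != 19:
        raise CqTableError(f"call-matrix fixture corrupted: {len(genes)} genes")
    if sorted(df["tissue"].unique()) != ["leaf", "root"]:
        raise CqTableError("call-matrix fixture corrupted: bad tissue levels")
    if len(df) != 38 or df.duplicated(["gene_id", "tissue"]).any():
        raise CqTableError("call-matrix fixture corrupted: bad row set")
    for col in ("pattern_tolerant", "pattern_sensitive"):
        if not set(df[col]) <= _PATTERNS:
            raise CqTableError(f"call-matrix fixture corrupted: bad {col}")
    for col in df.columns[df.columns.str.startswith("contrast_")]:
        if not set(df[col]) <= _CONTRASTS:
            raise CqTableError(f"call-matrix fixture corrupted: bad {col}")
    for col in df.columns[df.columns.str.startswith("dir_")]:
        if not set(df[col]) <= _DIRS:
            raise CqTableError(f"call-matrix fixture corrupted: bad {col}")
    # per-timepoint directions must be consistent with the recorded pattern
    for _, r in df.iterrows():
        for side, cols in (
            ("pattern_tolerant", ("dir_tol_2h", "dir_tol_5h")),
            ("pattern_sensitive", ("dir_sens_2h", "dir_sens_5h")),
        ):
            dirs = {r[c] for c in cols}
            if "up" in dirs and "down" in dirs:
                derived = "mixed"
            elif "up" in dirs:
                derived = "up"
            elif "down" in dirs:
                derived = "down"
            else:
                derived = "unchanged"
            if derived != r[side]:
                raise CqTableError(
                    f"call-matrix fixture corrupted: {r['gene_id']} {r['tissue']} "
                    f"{side}={r[side]} but per-timepoint directions give {derived}"
                )


def load_paper_call_matrix() -> "StateMatrix":
    """The qualitative 19-gene × 2-tissue state matrix of the published screen.

    Repeated calls return equal structures; the fixture is integrity-checked
    on every load.
    """
    from drqpcr.candidate_selection import StateMatrix, StateRow

    df = load_paper_call_table()
    rows = {}
    for _, r in df.iterrows():
        contrasts = {
            (trt, tp): r[f"contrast_{trt}_{int(tp)}h"] for trt, tp in _CELLS
        }
        ambiguous = frozenset(
            () if r["ambiguous"] == "-" else str(r["ambiguous"]).split(",")
        )
        rows[(r["gene_id"], r["tissue"])] = StateRow(
            gene_id=r["gene_id"],
            tissue=r["tissue"],
            pattern_tolerant=r["pattern_tolerant"],
            pattern_sensitive=r["pattern_sensitive"],
            contrasts=contrasts,
            ambiguous_cells=ambiguous,
        )
    return StateMatrix(rows=rows, timepoints=(2.0, 5.0))
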