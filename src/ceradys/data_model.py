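"""Core data types and delimited-text I/O.

Expression matrices are genes x samples on a log2 scale; transcript class
(mRNA / lncRNA / miRNA) is a property of the matrix a gene is loaded into,
not of an annotation database. Inputs are assumed already normalized and
log2-transformed; no normalization is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ceradys")

TRANSCRIPT_CLASSES = ("mRNA", "lncRNA", "miRNA")

#: text precision used by every TSV writer; 17 significant digits
#: round-trips IEEE doubles bit-identically.
FLOAT_FORMAT = "%.17g"


class DataModelError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    df : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, float values.
    transcript_class : str
        One of ``"mRNA"``, ``"lncRNA"``, ``"miRNA"``.
    """

    df: pd.DataFrame
    transcript_class: str

    def __post_init__(self) -> None:
        if self.transcript_class not in TRANSCRIPT_CLASSES:
            raise DataModelError(
                f"unknown transcript class {self.transcript_class!r}; "
                f"expected one of {TRANSCRIPT_CLASSES}"
            )
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicated gene ids: {dups[:5]}")
        if self.df.columns.duplicated().any():
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise DataModelError(f"duplicated sample ids: {dups[:5]}")
        if self.df.empty:
            raise DataModelError("empty expression matrix")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataModelError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataModelError(
                f"non-finite value at gene {self.df.index[bad[0]]!r}, "
                f"sample {self.df.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (in that order)."""
        missing = [s for s in sample_ids if s not in self.df.columns]
        if missing:
            raise DataModelError(
                f"samples absent from {self.transcript_class} matrix: {missing[:5]}"
            )
        return ExpressionMatrix(self.df.loc[:, list(sample_ids)], self.transcript_class)

    def row(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.df.index:
            raise DataModelError(
                f"gene {gene_id!r} absent from {self.transcript_class} matrix"
            )
        return self.df.loc[gene_id].to_numpy(dtype=float)

    def write(self, path: str | Path) -> None:
        """Write as TSV (gene id in the first column, header row)."""
        out = self.df.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


@dataclass
class SampleMetadata:
    """Sample -> group (and optional outcome) assignments.

    ``group`` is ``"control"`` or a stage label (S1..Sk); ``outcome`` is
    ``"HF"`` / ``"non-HF"`` or missing.
    """

    df: pd.DataFrame  # columns: sample_id, group, outcome

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        if not required.issubset(self.df.columns):
            raise DataModelError(
                f"metadata must have columns {sorted(required)}; "
                f"got {list(self.df.columns)}"
            )
        if "outcome" not in self.df.columns:
            self.df = self.df.assign(outcome=pd.NA)
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise DataModelError(f"duplicated sample ids in metadata: {list(dups)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.df.loc[self.df["group"] == group, "sample_id"])

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.df["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def outcome_of(self, sample_id: str) -> Optional[str]:
        row = self.df.loc[self.df["sample_id"] == sample_id, "outcome"]
        if row.empty or pd.isna(row.iloc[0]):
            return None
        return str(row.iloc[0])

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class InteractionSet:
    """Experimentally supported miRNA -> target maps."""

    mirna_to_mrna: dict[str, set[str]] = field(default_factory=dict)
    mirna_to_lncrna: dict[str, set[str]] = field(default_factory=dict)

    def mirnas(self) -> set[str]:
        """Distinct miRNAs with at least one interaction of either kind."""
        return set(self.mirna_to_mrna) | set(self.mirna_to_lncrna)

    def mirnas_targeting_mrna(self, mrna: str) -> set[str]:
        return {m for m, tgts in self.mirna_to_mrna.items() if mrna in tgts}

    def mirnas_targeting_lncrna(self, lncrna: str) -> set[str]:
        return {m for m, tgts in self.mirna_to_lncrna.items() if lncrna in tgts}

    def restrict_to(
        self,
        mirnas: Optional[Iterable[str]] = None,
        mrnas: Optional[Iterable[str]] = None,
        lncrnas: Optional[Iterable[str]] = None,
    ) -> "InteractionSet":
        """Drop interactions whose members are outside the given universes."""
        mi = set(mirnas) if mirnas is not None else None
        mr = set(mrnas) if mrnas is not None else None
        ln = set(lncrnas) if lncrnas is not None else None
        out = InteractionSet()
        for m, tgts in self.mirna_to_mrna.items():
            if mi is not None and m not in mi:
                continue
            kept = tgts if mr is None else tgts & mr
            if kept:
                out.mirna_to_mrna[m] = set(kept)
        for m, tgts in self.mirna_to_lncrna.items():
            if mi is not None and m not in mi:
                continue
            kept = tgts if ln is None else tgts & ln
            if kept:
                out.mirna_to_lncrna[m] = set(kept)
        return out

    def n_pairs(self) -> tuple[int, int]:
        return (
            sum(len(t) for t in self.mirna_to_mrna.values()),
            sum(len(t) for t in self.mirna_to_lncrna.values()),
        )


# ---------------------------------------------------------------------------
# readers


def _sniff_delimiter(path: Path) -> str:
    """Choose tab or comma from the header line; ties go to tab."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene id to their elementwise median.

    First-appearance order of gene ids is preserved, so the result does
    not depend on the input row order beyond which id came first.
    """
    if not df.index.duplicated().any():
        return df
    order = df.index.unique()
    collapsed = df.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def read_expression(path: str | Path, transcript_class: str) -> ExpressionMatrix:
    """Read a genes-in-rows delimited expression table.

    The first column holds gene ids, the remaining columns one sample each;
    a header row is required. Duplicate gene ids are collapsed to their
    per-sample median.
    """
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"expression file not found: {path}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise DataModelError(f"empty expression matrix in {path}")
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise DataModelError(
                    f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
                ) from None
        raise
    df.index = df.index.astype(str)
    n_raw = len(df)
    df = collapse_duplicates(df)
    mat = ExpressionMatrix(df, transcript_class)
    logger.info(
        "read %s matrix %s: %d genes (%d rows before collapse) x %d samples",
        transcript_class, path.name, len(df), n_raw, df.shape[1],
    )
    return mat


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    return SampleMetadata(df)


def _read_pairs(path: Path) -> dict[str, set[str]]:
    if not path.exists():
        raise DataModelError(f"interaction file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    if df.empty:
        raise DataModelError(f"empty interaction file: {path}")
    if df.shape[1] < 2:
        raise DataModelError(f"interaction file needs 2 columns, got {df.shape[1]}: {path}")
    out: dict[str, set[str]] = {}
    for mirna, target in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(mirna), set()).add(str(target))
    return out


def read_interactions(path_mrna: str | Path, path_lncrna: str | Path) -> InteractionSet:
    """Read two-column (miRNA, target) tables; duplicates are dropped."""
    inter = InteractionSet(
        mirna_to_mrna=_read_pairs(Path(path_mrna)),
        mirna_to_lncrna=_read_pairs(Path(path_lncrna)),
    )
    n_mr, n_ln = inter.n_pairs()
    logger.info(
        "read interactions: %d miRNA-mRNA pairs (%d miRNAs), "
        "%d miRNA-lncRNA pairs (%d miRNAs)",
        n_mr, len(inter.mirna_to_mrna), n_ln, len(inter.mirna_to_lncrna),
    )
    return inter


def write_interactions(
    inter: InteractionSet, path_mrna: str | Path, path_lncrna: str | Path
) -> None:
    for mapping, path, col in (
        (inter.mirna_to_mrna, path_mrna, "mrna"),
        (inter.mirna_to_lncrna, path_lncrna, "lncrna"),
    ):
        rows = [
            {"mirna": m, col: t}
            for m in sorted(mapping)
            for t in sorted(mapping[m])
        ]
        pd.DataFrame(rows, columns=["mirna", col]).to_csv(path, sep="\t", index=False)


def align_samples(
    matrices: Sequence[ExpressionMatrix], metadata: Optional[SampleMetadata] = None
) -> list[ExpressionMatrix]:
    """Restrict all matrices to the ordered intersection of their samples.

    Samples present in some but not all matrices (or absent from the
    metadata) are dropped with a log message.
    """
    common = [s for s in matrices[0].sample_ids
              if all(s in m.df.columns for m in matrices[1:])]
    if metadata is not None:
        known = set(metadata.sample_ids)
        common = [s for s in common if s in known]
    if not common:
        raise DataModelError("no samples shared by all matrices")
    for m in matrices:
        dropped = [s for s in m.sample_ids if s not in set(common)]
        if dropped:
            logger.info(
                "dropping %d %s samples absent elsewhere: %s%s",
                len(dropped), m.transcript_class, dropped[:5],
                "..." if len(dropped) > 5 else "",
            )
    return [m.subset_samples(common) for m in matrices]
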