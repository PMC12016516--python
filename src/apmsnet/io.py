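"""Data model and TSV readers/writers for AP-MS spectral-count experiments.

The central observable is the spectral count: the number of MS/MS spectra
assigned to peptides of a protein in one LC-MS/MS run, a semi-quantitative
proxy for protein abundance in the purified fraction.  A
:class:`SpectralCountTable` holds these counts (proteins x runs) and a
:class:`SampleSheet` binds each run to its strain (a tagged bait gene or the
untagged parental control), growth condition (presence/absence of elemental
sulfur and of pyruvate) and replicate index.

All on-disk formats are tab-separated UTF-8 with an explicit header row.
Missing values are disallowed in count tables: zeros must be written out.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARENTAL = "PARENTAL"

_TK_ID = re.compile(r"^TK\d{4}$")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. counts and sample sheet) do not."""


class MissingGroupError(LookupError):
    """No experimental runs exist for the requested bait/condition."""


class MissingControlError(LookupError):
    """No parental control runs exist for the requested condition."""


@dataclass(frozen=True)
class Condition:
    """A growth condition: presence of elemental sulfur and of pyruvate.

    Sulfur is the organism's preferred terminal electron acceptor, so the
    +S/-S contrast is the study's main redox axis; pyruvate is varied only
    for the glycolytic bait (GAPOR), hence two independent booleans.
    """

    sulfur: bool
    pyruvate: bool = True

    def label(self) -> str:
        s = "+S" if self.sulfur else "-S"
        p = "+P" if self.pyruvate else "-P"
        return f"{s}{p}"


@dataclass
class SampleSheet:
    """Run metadata: one row per MS run.

    Columns: run_id, strain (tagged gene id or ``PARENTAL``), role
    (``experimental`` | ``control``), sulfur, pyruvate (booleans),
    replicate (positive integer).
    """

    frame: pd.DataFrame

    REQUIRED = ("run_id", "strain", "role", "sulfur", "pyruvate", "replicate")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df["run_id"].duplicated().any():
            dupes = sorted(df.loc[df["run_id"].duplicated(), "run_id"])
            raise ConsistencyError(f"duplicate run_id(s) in sample sheet: {dupes}")
        bad_role = set(df["role"]) - {"experimental", "control"}
        if bad_role:
            raise FormatError(f"unknown role value(s): {sorted(bad_role)}")
        if (df["replicate"] < 1).any():
            raise FormatError("replicate indices must be positive integers")
        key = df[["strain", "sulfur", "pyruvate", "replicate"]]
        if key.duplicated().any():
            raise ConsistencyError(
                "duplicate (strain, sulfur, pyruvate, replicate) in sample sheet"
            )
        ctrl_strains = set(df.loc[df["role"] == "control", "strain"])
        if ctrl_strains - {PARENTAL}:
            raise ConsistencyError(
                f"control runs must reference {PARENTAL!r}, got {sorted(ctrl_strains)}"
            )

    @property
    def run_ids(self) -> list[str]:
        return list(self.frame["run_id"])

    def baits(self) -> list[str]:
        """Tagged strains present among experimental runs, in sheet order."""
        exp = self.frame[self.frame["role"] == "experimental"]
        return list(dict.fromkeys(exp["strain"]))

    def conditions_for(self, bait: str) -> list[Condition]:
        exp = self.frame[
            (self.frame["role"] == "experimental") & (self.frame["strain"] == bait)
        ]
        seen = dict.fromkeys(
            (bool(s), bool(p)) for s, p in zip(exp["sulfur"], exp["pyruvate"])
        )
        return [Condition(s, p) for s, p in seen]

    def runs(self, *, strain: str | None = None, role: str | None = None,
             condition: Condition | None = None) -> list[str]:
        df = self.frame
        mask = pd.Series(True, index=df.index)
        if strain is not None:
            mask &= df["strain"] == strain
        if role is not None:
            mask &= df["role"] == role
        if condition is not None:
            mask &= (df["sulfur"] == condition.sulfur) & (
                df["pyruvate"] == condition.pyruvate
            )
        return list(df.loc[mask, "run_id"])


@dataclass
class SpectralCountTable:
    """Non-negative integer spectral counts, proteins x runs.

    ``frame`` is indexed by protein identifier with one column per run.
    Rows that are zero in every run are legal observations and are kept.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.duplicated().any():
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise ConsistencyError(f"duplicate protein_id(s): {dupes}")
        if df.columns.duplicated().any():
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise ConsistencyError(f"duplicate run_id(s): {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("spectral counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at protein {df.index[i]!r}, run {df.columns[j]!r}"
            )
        nonconforming = [p for p in df.index if not _TK_ID.match(str(p))]
        if nonconforming:
            warnings.warn(
                f"{len(nonconforming)} protein id(s) do not follow the TKxxxx "
                f"convention (e.g. {nonconforming[0]!r}); proceeding anyway",
                stacklevel=2,
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.frame.columns)

    def counts(self, runs: list[str]) -> np.ndarray:
        """Counts sub-matrix (proteins x len(runs)) for the given runs."""
        return self.frame[runs].to_numpy()


@dataclass
class TargetTable:
    """Tagged bait genes with their complex membership and tag terminus."""

    frame: pd.DataFrame

    REQUIRED = ("gene_id", "complex_acronym", "subunit", "tag_terminus")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"target table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            raise ConsistencyError("duplicate gene_id in target table")
        bad = set(df["tag_terminus"]) - {"C", "N"}
        if bad:
            raise FormatError(f"tag_terminus must be C or N, got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])

    def complexes(self) -> dict[str, list[str]]:
        """Map complex acronym -> member bait genes.

        A slash-separated acronym (e.g. ``VOR/POR`` for a shared subunit)
        places the gene in every listed complex.
        """
        out: dict[str, list[str]] = {}
        for gene, acronyms in zip(self.frame["gene_id"], self.frame["complex_acronym"]):
            for name in str(acronyms).split("/"):
                out.setdefault(name, []).append(gene)
        return out


# ---------------------------------------------------------------------------
# readers / writers

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_bool(value: object, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise FormatError(f"cannot parse boolean {value!r} in column {column!r}")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SampleSheet.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns: {missing}")
    for col in ("sulfur", "pyruvate"):
        df[col] = [_parse_bool(v, col) for v in df[col]]
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate index in {path}: {exc}") from exc
    return SampleSheet(df.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = sheet.frame.copy()
    for col in ("sulfur", "pyruvate"):
        df[col] = np.where(df[col], "true", "false")
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path, sheet: SampleSheet) -> SpectralCountTable:
    """Read a protein x run count TSV and validate it against the sheet.

    The first column holds protein identifiers; every other column header is
    a run_id that must appear in ``sheet``.  Cells must be non-negative
    integers; fractional or missing values are format errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"missing count value at protein {row!r} in {path}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise FormatError(
                f"non-numeric count at protein {row!r}, run {col!r} in {path}"
            )
        if (vals % 1 != 0).any():
            row = df.index[vals % 1 != 0][0]
            raise FormatError(
                f"non-integer count at protein {row!r}, run {col!r} in {path}"
            )
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = "protein_id"
    unknown = [r for r in df.columns if r not in set(sheet.run_ids)]
    if unknown:
        raise ConsistencyError(
            f"run(s) {unknown} in count table absent from sample sheet"
        )
    return SpectralCountTable(df)


def write_count_table(table: SpectralCountTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="protein_id")


def read_target_table(path) -> TargetTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TargetTable(df.reset_index(drop=True))


def write_target_table(table: TargetTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def select_group(
    table: SpectralCountTable,
    sheet: SampleSheet,
    bait: str,
    condition: Condition,
) -> tuple[list[str], list[str]]:
    """Resolve the experimental and control run groups for one comparison.

    Experimental runs come from the tagged strain of ``bait``; controls are
    the parental-strain purifications matched to the same condition (the
    untagged near-isogenic strain purified identically, which subtracts
    proteins with natural affinity for the IMAC resin).
    """
    exp = sheet.runs(strain=bait, role="experimental", condition=condition)
    if not exp:
        raise MissingGroupError(
            f"no experimental runs for bait {bait!r} in {condition.label()}"
        )
    ctrl = sheet.runs(strain=PARENTAL, role="control", condition=condition)
    if not ctrl:
        raise MissingControlError(
            f"no parental control runs for condition {condition.label()}"
        )
    present = set(table.run_ids)
    exp = [r for r in exp if r in present]
    ctrl = [r for r in ctrl if r in present]
    if not exp:
        raise MissingGroupError(
            f"experimental runs for {bait!r} in {condition.label()} "
            "absent from count table"
        )
    if not ctrl:
        raise MissingControlError(
            f"control runs for {condition.label()} absent from count table"
        )
    return exp, ctrl
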