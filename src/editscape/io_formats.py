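"""Readers, writers and label derivation for every file the pipeline touches.

All tabular formats are TSV; sequences are FASTA. Editing matrices are
sites x samples with values in [0, 1]; a missing measurement is an empty
cell (``"NA"`` is also accepted on input). Readers validate and reject
rather than coerce, so downstream stages can assume clean data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Closed vocabulary of transcribed regions an editing site can fall in.
REGIONS = ("3'-UTR", "5'-UTR", "exonic", "intronic", "intergenic", "ncRNA")

#: Clinical response labels used to define resistant / sensitive samples.
RESISTANT_LABEL = "Progressive Disease"
SENSITIVE_LABEL = "Complete Response"


@dataclass
class EditingProfile:
    """A sites x samples matrix of per-site editing levels.

    ``levels`` is a DataFrame indexed by site id with sample ids as
    columns; NaN marks a missing measurement. Every non-missing value
    lies in [0, 1].
    """

    levels: pd.DataFrame

    @property
    def site_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.levels.columns)

    def validate(self) -> "EditingProfile":
        idx = self.levels.index
        cols = self.levels.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate site id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        bad = (self.levels < 0) | (self.levels > 1)
        if bad.any().any():
            col = bad.any(axis=0).idxmax()
            row = bad[col].idxmax()
            raise ValueError(
                f"editing level out of [0, 1] at site {row!r}, sample {col!r}: "
                f"{self.levels.loc[row, col]}"
            )
        return self


@dataclass(frozen=True)
class Condition:
    """One (cancer, drug) pair with labeled resistant/sensitive samples."""

    cancer: str
    drug: str
    resistant: frozenset[str]
    sensitive: frozenset[str]

    def __post_init__(self) -> None:
        if self.resistant & self.sensitive:
            raise ValueError(
                f"condition {self.name}: samples in both groups: "
                f"{sorted(self.resistant & self.sensitive)}"
            )

    @property
    def name(self) -> str:
        return f"{self.cancer}-{self.drug}"

    @property
    def samples(self) -> frozenset[str]:
        return self.resistant | self.sensitive


@dataclass
class CellLineResponse:
    cell_line: str
    compound: str
    ln_ic50: float
    z: float
    label: str  # resistant | sensitive | intermediate


# ---------------------------------------------------------------------------
# editing matrix


def read_editing_matrix(path: str | Path) -> EditingProfile:
    levels = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["", "NA"],
        keep_default_na=False,
    )
    try:
        levels = levels.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric editing level: {exc}") from exc
    levels.index = levels.index.astype(str)
    levels.index.name = "site_id"
    return EditingProfile(levels).validate()


def write_editing_matrix(profile: EditingProfile, path: str | Path) -> None:
    out = profile.levels.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# drug response labels and conditions


def label_tumor_samples(response: pd.DataFrame) -> pd.DataFrame:
    """Map clinical response labels to resistant/sensitive groups.

    Only the two labels the analysis uses are kept: "Progressive Disease"
    becomes ``resistant`` and "Complete Response" becomes ``sensitive``.
    Any other response label (partial response, stable disease, ...) is
    excluded; the number dropped is logged.
    """
    required = {"sample", "cancer", "drug", "response_label"}
    missing = required - set(response.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    mapping = {RESISTANT_LABEL: "resistant", SENSITIVE_LABEL: "sensitive"}
    labeled = response.copy()
    labeled["group"] = labeled["response_label"].map(mapping)
    dropped = labeled["group"].isna().sum()
    if dropped:
        log.info("label_tumor_samples: excluded %d samples with other labels", dropped)
    return labeled.dropna(subset=["group"]).reset_index(drop=True)


def build_conditions(labeled: pd.DataFrame, min_per_group: int = 3) -> list[Condition]:
    """Group labeled samples into (cancer, drug) conditions.

    A condition is kept only when both the resistant and the sensitive
    group have at least ``min_per_group`` samples; all others are dropped
    (and logged). The result is sorted by (cancer, drug) so it does not
    depend on input row order.
    """
    conditions: list[Condition] = []
    for (cancer, drug), grp in sorted(labeled.groupby(["cancer", "drug"], sort=True)):
        res = frozenset(grp.loc[grp["group"] == "resistant", "sample"])
        sen = frozenset(grp.loc[grp["group"] == "sensitive", "sample"])
        if len(res) >= min_per_group and len(sen) >= min_per_group:
            conditions.append(Condition(str(cancer), str(drug), res, sen))
        else:
            log.info(
                "build_conditions: dropped %s-%s (%d resistant, %d sensitive)",
                cancer, drug, len(res), len(sen),
            )
    return conditions


def label_cell_lines(ic50: pd.DataFrame, z_cut: float = 0.8) -> list[CellLineResponse]:
    """Classify cell lines by z-scored ln(IC50) within each compound.

    z uses the sample standard deviation (ddof=1). A line is resistant
    when z > ``z_cut``, sensitive when z < -``z_cut`` and intermediate
    otherwise (strict inequalities: |z| exactly at the cut is
    intermediate).
    """
    required = {"cell_line", "compound", "ln_ic50"}
    missing = required - set(ic50.columns)
    if missing:
        raise ValueError(f"ln(IC50) table missing columns: {sorted(missing)}")
    out: list[CellLineResponse] = []
    for compound, grp in ic50.groupby("compound", sort=True):
        sd = grp["ln_ic50"].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"compound {compound!r}: zero ln(IC50) variance")
        mean = grp["ln_ic50"].mean()
        for _, row in grp.iterrows():
            z = (row["ln_ic50"] - mean) / sd
            if z > z_cut:
                label = "resistant"
            elif z < -z_cut:
                label = "sensitive"
            else:
                label = "intermediate"
            out.append(
                CellLineResponse(str(row["cell_line"]), str(compound),
                                 float(row["ln_ic50"]), float(z), label)
            )
    return out


# ---------------------------------------------------------------------------
# annotation / expression / survival / FASTA


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a site annotation table indexed by site id.

    Columns: chrom, pos (1-based), strand, gene_id (empty for
    intergenic), region (from the closed vocabulary).
    """
    ann = pd.read_csv(
        path, sep="\t", dtype={"site_id": str, "chrom": str, "gene_id": str},
        na_values=[""], keep_default_na=False,
    )
    required = {"site_id", "chrom", "pos", "strand", "gene_id", "region"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    for i, row in ann.iterrows():
        line = i + 2  # header is line 1
        if row["region"] not in REGIONS:
            raise ValueError(f"line {line}: unknown region {row['region']!r}")
        if not row["pos"] >= 1:
            raise ValueError(f"line {line}: position must be >= 1, got {row['pos']}")
        if row["strand"] not in ("+", "-"):
            raise ValueError(f"line {line}: strand must be + or -, got {row['strand']!r}")
        if row["region"] == "intergenic" and isinstance(row["gene_id"], str) and row["gene_id"]:
            raise ValueError(f"line {line}: intergenic site {row['site_id']!r} has a gene id")
    if ann["site_id"].duplicated().any():
        dup = ann.loc[ann["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"duplicate site id in annotation: {dup!r}")
    ann = ann.set_index("site_id")
    ann["gene_id"] = ann["gene_id"].replace({pd.NA: ""}).fillna("")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t")


def write_bed(ann: pd.DataFrame, path: str | Path) -> None:
    """Export site positions as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for site_id, row in ann.iterrows():
            start = int(row["pos"]) - 1
            fh.write(f"{row['chrom']}\t{start}\t{start + 1}\t{site_id}\t0\t{row['strand']}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples expression table (values >= 0)."""
    expr = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    expr.index = expr.index.astype(str)
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    if (expr < 0).any().any():
        bad = (expr < 0).any(axis=1).idxmax()
        raise ValueError(f"negative expression value for feature {bad!r}")
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table (sample, time, event) with time > 0, event in {0, 1}."""
    surv = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "time", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    for i, row in surv.iterrows():
        line = i + 2
        if not row["time"] > 0:
            raise ValueError(f"line {line}: survival time must be > 0, got {row['time']}")
        if row["event"] not in (0, 1):
            raise ValueError(f"line {line}: event must be 0 or 1, got {row['event']}")
    if surv["sample"].duplicated().any():
        dup = surv.loc[surv["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample in survival table: {dup!r}")
    surv["event"] = surv["event"].astype(int)
    return surv.reset_index(drop=True)


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping (ids must be unique)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_response(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_response(response: pd.DataFrame, path: str | Path) -> None:
    response.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
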