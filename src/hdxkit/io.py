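"""File formats: uptake tables, peak lists, FASTA, and summary tables.

The uptake-table dialect is a DynamX-cluster-style CSV with columns
``peptide_id, sequence, start, end, state, exposure_min, replicate,
centroid_mass_da, charge`` — comma separated, header line, '.' decimal
separator, UTF-8.  Exposure-0 rows (reserved state ``ND``) define the
undeuterated mass; reserved state ``maxD`` carries the maximum-labeled
control.  Peak lists are two-column TSVs (``mz``, ``intensity``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .envelopes import IsotopicEnvelope, Peptide
from .synthetic import MAXLABEL_STATE, UNDEUTERATED_STATE

__all__ = [
    "UPTAKE_COLUMNS",
    "UptakeTable",
    "read_uptake_table",
    "write_uptake_table",
    "read_peak_list",
    "write_peak_list",
    "read_fasta",
    "write_fasta",
    "write_summary_tables",
]

UPTAKE_COLUMNS = (
    "peptide_id",
    "sequence",
    "start",
    "end",
    "state",
    "exposure_min",
    "replicate",
    "centroid_mass_da",
    "charge",
)


@dataclass
class UptakeTable:
    """Validated uptake table plus row-level diagnostics for rejects."""

    frame: pd.DataFrame
    peptides: dict[str, Peptide]
    rejected: list[str] = field(default_factory=list)

    def m0(self, peptide_id: str) -> float:
        """Mean undeuterated centroid mass of a peptide."""
        sel = self.frame[
            (self.frame["peptide_id"] == peptide_id)
            & (self.frame["state"] == UNDEUTERATED_STATE)
        ]
        if sel.empty:
            raise KeyError(f"no undeuterated rows for {peptide_id}")
        return float(sel["centroid_mass_da"].mean())

    def maxlabel(self, peptide_id: str) -> float:
        """Mean maximum-labeled control centroid mass of a peptide."""
        sel = self.frame[
            (self.frame["peptide_id"] == peptide_id)
            & (self.frame["state"] == MAXLABEL_STATE)
        ]
        if sel.empty:
            raise KeyError(f"no maximum-labeled rows for {peptide_id}")
        return float(sel["centroid_mass_da"].mean())

    def uptake(self) -> pd.DataFrame:
        """Per-replicate deuterium uptake (Da) for the experimental states.

        Columns: peptide_id, state, exposure_min, replicate, uptake_da.
        """
        rows = []
        for pid in self.peptides:
            m0 = self.m0(pid)
            sel = self.frame[
                (self.frame["peptide_id"] == pid)
                & ~self.frame["state"].isin([UNDEUTERATED_STATE, MAXLABEL_STATE])
            ]
            for _, r in sel.iterrows():
                rows.append(
                    {
                        "peptide_id": pid,
                        "state": r["state"],
                        "exposure_min": float(r["exposure_min"]),
                        "replicate": int(r["replicate"]),
                        "uptake_da": float(r["centroid_mass_da"]) - m0,
                    }
                )
        return pd.DataFrame(rows)


def write_uptake_table(frame: pd.DataFrame, path: str | Path) -> None:
    missing = set(UPTAKE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"uptake table missing columns: {sorted(missing)}")
    frame.loc[:, UPTAKE_COLUMNS].to_csv(path, index=False)


def read_uptake_table(path: str | Path) -> UptakeTable:
    """Read and validate an uptake CSV.

    Malformed rows (negative masses, non-numeric fields, inconsistent
    spans) are collected into ``rejected`` with a row-level diagnostic;
    a missing required column or two peptides sharing an id with
    conflicting spans is a hard error.
    """
    raw = pd.read_csv(path)
    missing = set(UPTAKE_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    rejected: list[str] = []
    keep_idx = []
    for idx, row in raw.iterrows():
        try:
            mass = float(row["centroid_mass_da"])
            if not np.isfinite(mass) or mass <= 0:
                raise ValueError(f"non-positive centroid mass {mass!r}")
            if float(row["exposure_min"]) < 0:
                raise ValueError("negative exposure")
            int(row["start"]), int(row["end"]), int(row["replicate"])
        except (TypeError, ValueError) as exc:
            rejected.append(f"row {idx}: {exc}")
            continue
        keep_idx.append(idx)
    frame = raw.loc[keep_idx].copy()
    frame["exposure_min"] = frame["exposure_min"].astype(float)
    frame["centroid_mass_da"] = frame["centroid_mass_da"].astype(float)

    peptides: dict[str, Peptide] = {}
    for pid, grp in frame.groupby("peptide_id", sort=True):
        spans = grp[["sequence", "start", "end"]].drop_duplicates()
        if len(spans) != 1:
            raise ValueError(f"{path}: conflicting span/sequence for peptide {pid!r}")
        seq, start, _ = spans.iloc[0]
        peptides[str(pid)] = Peptide.from_sequence(str(pid), str(seq), int(start))
    return UptakeTable(frame=frame, peptides=peptides, rejected=rejected)


def write_peak_list(envelope: IsotopicEnvelope, path: str | Path) -> None:
    pd.DataFrame({"mz": envelope.mz, "intensity": envelope.intensity}).to_csv(
        path, sep="\t", index=False
    )


def read_peak_list(path: str | Path, charge: int) -> IsotopicEnvelope:
    frame = pd.read_csv(path, sep="\t")
    for col in ("mz", "intensity"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return IsotopicEnvelope(
        mz=frame["mz"].to_numpy(float),
        intensity=frame["intensity"].to_numpy(float),
        charge=charge,
    )


def read_fasta(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq)


def write_fasta(sequence: str, path: str | Path, record_id: str = "protein") -> None:
    SeqIO.write(
        [SeqRecord(Seq(sequence), id=record_id, description="")], str(path), "fasta"
    )


def write_summary_tables(
    table: UptakeTable,
    design,
    sequence_length: int,
    outdir: str | Path,
    back_exchange: dict[str, float] | None = None,
) -> tuple[Path, Path]:
    """Write the study-level summary and the per-peptide data table.

    The summary records the deuterium content during labeling, time
    points, replicate counts, per-peptide back-exchange (mean and range,
    when supplied) and sequence coverage; the data table lists mean
    uptake and SD per peptide x state x time.  Follows the layout of the
    community-recommended HDX summary/data tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    covered = np.zeros(sequence_length, dtype=bool)
    for pep in table.peptides.values():
        covered[pep.start - 1 : pep.end] = True
    coverage_pct = 100.0 * covered.sum() / sequence_length if sequence_length else 0.0

    be_vals = list(back_exchange.values()) if back_exchange else []
    summary = pd.DataFrame(
        [
            ("deuterium_content_pct", round(design.label_fraction * 100.0, 4)),
            ("exposure_times_min", ";".join(f"{t:g}" for t in design.times_min)),
            ("replicates", design.replicates),
            ("n_peptides", len(table.peptides)),
            ("sequence_coverage_pct", round(coverage_pct, 1)),
            (
                "back_exchange_mean_pct",
                round(float(np.mean(be_vals)), 2) if be_vals else "",
            ),
            (
                "back_exchange_range_pct",
                f"{min(be_vals):.2f}-{max(be_vals):.2f}" if be_vals else "",
            ),
        ],
        columns=["field", "value"],
    )
    summary_path = outdir / "hdx_summary.csv"
    summary.to_csv(summary_path, index=False)

    uptake = table.uptake()
    if len(uptake):
        data = (
            uptake.groupby(["peptide_id", "state", "exposure_min"])["uptake_da"]
            .agg(uptake_mean_da="mean", uptake_sd_da=lambda v: v.std(ddof=1))
            .reset_index()
        )
    else:
        data = pd.DataFrame(
            columns=["peptide_id", "state", "exposure_min", "uptake_mean_da", "uptake_sd_da"]
        )
    data_path = outdir / "hdx_data.csv"
    data.to_csv(data_path, index=False)
    return summary_path, data_path
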