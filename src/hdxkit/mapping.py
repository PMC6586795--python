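"""Peptide-to-residue consolidation and structure annotation.

Peptide-level HDX values are projected onto residues with a
shortest-peptide-wins rule (the shortest covering peptide is the most
localized measurement; ties go to the later-starting peptide), and the
resulting per-residue values can be written into the B-factor column of a
PDB structure for visualization, with a -1.00 sentinel marking residues
not covered by any peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .envelopes import Peptide

__all__ = ["ResidueMap", "map_to_residues", "export_structure_annotation"]

UNCOVERED_SENTINEL = -1.00


@dataclass
class ResidueMap:
    """Per-residue values on a 1-based sequence frame."""

    values: np.ndarray  # float, NaN where uncovered
    covered: np.ndarray  # bool
    source_peptide: list[str | None]

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self) + 1),
                "value": self.values,
                "covered": self.covered,
                "source_peptide": self.source_peptide,
            }
        )


def map_to_residues(
    values: dict[str, float],
    peptides: dict[str, Peptide],
    sequence_length: int,
) -> ResidueMap:
    """Assign each residue the value of its most localized covering peptide.

    Residues covered by several peptides take the value of the shortest
    one; among equally short peptides the one starting later wins.
    Residues with no covering peptide are flagged uncovered (NaN), never
    zero-filled.
    """
    out = np.full(sequence_length, np.nan)
    covered = np.zeros(sequence_length, dtype=bool)
    source: list[str | None] = [None] * sequence_length
    best_key: list[tuple[int, int] | None] = [None] * sequence_length

    for pid, value in values.items():
        pep = peptides[pid]
        if pep.start < 1 or pep.end > sequence_length:
            raise ValueError(
                f"{pid}: span {pep.start}-{pep.end} outside sequence of "
                f"length {sequence_length}"
            )
        # shorter peptide wins; ties -> later start (larger start preferred)
        key = (pep.end - pep.start + 1, -pep.start)
        for r in range(pep.start - 1, pep.end):
            if best_key[r] is None or key < best_key[r]:
                best_key[r] = key
                out[r] = value
                covered[r] = True
                source[r] = pid
    return ResidueMap(values=out, covered=covered, source_peptide=source)


def export_structure_annotation(
    residue_map: ResidueMap,
    structure_path: str | Path,
    out_pdb: str | Path,
    chain: str = "A",
    out_csv: str | Path | None = None,
) -> list[int]:
    """Write per-residue values into the B-factor column of a PDB file.

    Atoms of covered residues receive the mapped value; uncovered (or
    unmapped) residues get the -1.00 sentinel.  Residues present in the
    chain but outside the map's numbering are reported back as a
    mismatch list rather than silently dropped.
    """
    structure = gemmi.read_structure(str(structure_path))
    structure.setup_entities()
    mismatches: list[int] = []
    for model in structure:
        for ch in model:
            if ch.name != chain:
                continue
            for residue in ch:
                num = residue.seqid.num
                if 1 <= num <= len(residue_map) and residue_map.covered[num - 1]:
                    b = float(residue_map.values[num - 1])
                elif 1 <= num <= len(residue_map):
                    b = UNCOVERED_SENTINEL
                else:
                    mismatches.append(num)
                    b = UNCOVERED_SENTINEL
                for atom in residue:
                    atom.b_iso = b
    structure.write_pdb(str(out_pdb))
    if out_csv is not None:
        residue_map.to_frame().to_csv(out_csv, index=False)
    return mismatches
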