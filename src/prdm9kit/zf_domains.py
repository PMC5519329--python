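"""Parsing of C2H2 zinc-finger arrays from protein sequences.

A C2H2 zinc finger is modelled as the 28-residue unit

    X2-C-X2-C-X12-H-X3-H-X5

where X is any amino acid and the two cysteines / two histidines are the
zinc-coordinating anchors (1-based positions 3, 6, 19, 23).  Tandem arrays
of such units form the DNA-binding domain of PRDM9 and of C2H2 zinc-finger
genes generally; the diversity statistic downstream operates on arrays of
four or more adjacent fingers.

Matching is greedy, left-to-right and non-overlapping: a match consumes its
28 residues, so exact tandem repeats are recovered one finger at a time.
The ambiguity code X is accepted at any position except the four anchors.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from Bio import AlignIO

FINGER_LEN = 28
#: 0-based anchor positions and required residue (1-based 3, 6, 19, 23).
ANCHORS = {2: "C", 5: "C", 18: "H", 22: "H"}
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence, uppercase one-letter code (X allowed)."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains invalid characters {sorted(bad)}"
            )


@dataclasses.dataclass(frozen=True)
class ZincFinger:
    """A single 28-aa C2H2 unit at a 0-based offset in its parent protein."""

    sequence: str
    start: int

    def __post_init__(self) -> None:
        if len(self.sequence) != FINGER_LEN:
            raise ValueError(f"finger length {len(self.sequence)} != {FINGER_LEN}")
        for pos, aa in ANCHORS.items():
            if self.sequence[pos] != aa:
                raise ValueError(
                    f"anchor violation at 1-based position {pos + 1}: "
                    f"expected {aa}, got {self.sequence[pos]}"
                )

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence


@dataclasses.dataclass
class ZFArray:
    """An ordered run of adjacent fingers from one gene."""

    gene_id: str
    fingers: list[ZincFinger]
    is_first_array: bool = False

    def __len__(self) -> int:
        return len(self.fingers)

    @property
    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fingers]

    @property
    def has_ambiguous(self) -> bool:
        return any(f.has_ambiguous for f in self.fingers)


@dataclasses.dataclass(frozen=True)
class ResidueCheck:
    reference_position: int  # 1-based, ungapped reference coordinate
    reference_aa: str
    observed_aa: str | None
    is_substituted: bool | None
    alignable: bool


@dataclasses.dataclass
class CatalyticReport:
    gene_id: str
    entries: list[ResidueCheck]

    @property
    def any_substituted(self) -> bool:
        return any(e.is_substituted for e in self.entries if e.alignable)


def _matches_finger(window: str) -> bool:
    if len(window) != FINGER_LEN:
        return False
    return all(window[pos] == aa for pos, aa in ANCHORS.items())


def parse_zf_fingers(protein: ProteinRecord | str) -> list[ZincFinger]:
    """Extract every non-overlapping C2H2 finger, scanning left to right.

    Parameters
    ----------
    protein
        A :class:`ProteinRecord` or a raw sequence string.

    Returns
    -------
    Fingers with strictly increasing 0-based offsets.  A match consumes its
    28 residues, so the scan resumes immediately after each finger.
    """
    if isinstance(protein, str):
        protein = ProteinRecord(id="<anonymous>", sequence=protein)
    seq = protein.sequence
    fingers: list[ZincFinger] = []
    i = 0
    while i + FINGER_LEN <= len(seq):
        window = seq[i : i + FINGER_LEN]
        if _matches_finger(window):
            fingers.append(ZincFinger(sequence=window, start=i))
            i += FINGER_LEN
        else:
            i += 1
    return fingers


def extract_arrays(
    fingers: Sequence[ZincFinger],
    gap_tolerance: int = 0,
    min_fingers: int = 4,
    gene_id: str = "",
) -> list[ZFArray]:
    """Group fingers into maximal tandem runs and keep runs of >= min_fingers.

    Consecutive fingers belong to the same run when their starts differ by
    28 + g with 0 <= g <= ``gap_tolerance``.  The default tolerance of 0
    requires strictly abutting fingers (the trailing X5 of the motif is the
    inter-finger linker).  The first surviving run is flagged
    ``is_first_array``; when a gene has several spatially separated arrays
    only that first array feeds the diversity statistic.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if min_fingers < 1:
        raise ValueError("min_fingers must be >= 1")
    starts = [f.start for f in fingers]
    if starts != sorted(starts):
        raise ValueError("fingers must be sorted by offset")

    runs: list[list[ZincFinger]] = []
    for finger in fingers:
        if runs:
            gap = finger.start - runs[-1][-1].start - FINGER_LEN
            if 0 <= gap <= gap_tolerance:
                runs[-1].append(finger)
                continue
        runs.append([finger])

    arrays = [
        ZFArray(gene_id=gene_id, fingers=run)
        for run in runs
        if len(run) >= min_fingers
    ]
    if arrays:
        arrays[0].is_first_array = True
    return arrays


def fingers_table(records) -> "pandas.DataFrame":  # noqa: F821
    """Parse proteins into a long-format finger table.

    One row per finger with gene_id, array_index, finger_index, 0-based
    offset and sequence; fingers outside any qualifying array get array
    index -1.  ``records`` is a mapping or sequence of (id, sequence).
    """
    import pandas as pd

    items = records.items() if hasattr(records, "items") else records
    rows = []
    for gene_id, seq in items:
        fingers = parse_zf_fingers(seq)
        arrays = extract_arrays(fingers, gene_id=gene_id)
        membership = {}
        for ai, arr in enumerate(arrays):
            for f in arr.fingers:
                membership[f.start] = ai
        for fi, f in enumerate(fingers):
            rows.append(
                (gene_id, membership.get(f.start, -1), fi, f.start, f.sequence)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "array_index", "finger_index", "offset", "sequence"],
    )


def _reference_column_map(aligned_seq: str) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 0-based alignment columns."""
    mapping: dict[int, int] = {}
    pos = 0
    for col, aa in enumerate(aligned_seq):
        if aa != "-":
            pos += 1
            mapping[pos] = col
    return mapping


def check_catalytic_residues(
    alignment,
    reference_id: str,
    reference_positions: Iterable[int],
) -> list[CatalyticReport]:
    """Check residues of aligned sequences at reference-defined positions.

    Used to ask whether orthologs carry substitutions at the SET-domain
    catalytic tyrosines (the positions aligning to Y276, Y341 and Y357 of
    the human protein), but works for any aligned FASTA and position list.

    Parameters
    ----------
    alignment
        A ``Bio.Align.MultipleSeqAlignment`` or a path to an aligned FASTA.
    reference_id
        Record id of the reference sequence within the alignment.
    reference_positions
        1-based positions in the *ungapped* reference sequence.

    Returns
    -------
    One :class:`CatalyticReport` per non-reference sequence.  A query gap in
    the mapped column yields ``alignable=False`` with undefined (``None``)
    substitution status.
    """
    if isinstance(alignment, (str, bytes)) or hasattr(alignment, "__fspath__"):
        alignment = AlignIO.read(str(alignment), "fasta")
    records = {rec.id: str(rec.seq).upper() for rec in alignment}
    if reference_id not in records:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    ref_aligned = records[reference_id]
    colmap = _reference_column_map(ref_aligned)
    ref_len = len(colmap)
    positions = list(reference_positions)
    for pos in positions:
        if not 1 <= pos <= ref_len:
            raise ValueError(
                f"position {pos} outside reference sequence (length {ref_len})"
            )

    reports = []
    for rec_id, aligned in records.items():
        if rec_id == reference_id:
            continue
        entries = []
        for pos in positions:
            col = colmap[pos]
            ref_aa = ref_aligned[col]
            obs = aligned[col]
            if obs == "-":
                entries.append(
                    ResidueCheck(pos, ref_aa, None, None, alignable=False)
                )
            else:
                entries.append(
                    ResidueCheck(pos, ref_aa, obs, obs != ref_aa, alignable=True)
                )
        reports.append(CatalyticReport(gene_id=rec_id, entries=entries))
    return reports
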