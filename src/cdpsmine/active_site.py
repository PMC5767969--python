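"""Substrate-binding pocket residue extraction against a reference alignment.

A detected CDPS is aligned to a fixed reference alignment (profile-to-
sequence, so reference column numbering never changes between runs) and the
residues falling in the columns that carry the reference enzyme's P1 and P2
pocket positions are read off. Pocket positions are 1-based indices on the
ungapped reference (AlbC-style) sequence and ship as an editable data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hmmcore import GAP, ProfileHmm, SeedAlignment, build_profile, viterbi_align


@dataclass
class PocketMap:
    """P1/P2 pocket positions as 1-based indices on the ungapped reference."""

    P1: list[int]
    P2: list[int]

    def __post_init__(self) -> None:
        for name, idx in (("P1", self.P1), ("P2", self.P2)):
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"{name} indices must be strictly increasing")
            if any(i < 1 for i in idx):
                raise ValueError(f"{name} indices must be >= 1")
        if set(self.P1) & set(self.P2):
            raise ValueError("P1 and P2 must be disjoint")

    @classmethod
    def from_file(cls, path: str | Path) -> "PocketMap":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(P1=list(d["P1"]), P2=list(d["P2"]))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"P1": list(self.P1), "P2": list(self.P2)}, fh)


@dataclass
class ActiveSiteCall:
    protein_id: str
    P1_residues: str
    P2_residues: str
    aligned_columns: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class AugmentedAlignment:
    """A query row laid out on the reference alignment's column frame.

    ``query_row`` has one character per reference column ('-' where the
    query has no residue in that column); ``insertions`` records query
    residues that fell between reference columns, keyed by the preceding
    column index (-1 for an N-terminal insertion).
    """

    reference: SeedAlignment
    query_id: str
    query_row: str
    insertions: dict[int, str] = field(default_factory=dict)

    def rows_with_query(self) -> list[tuple[str, str]]:
        """Reference rows plus the query, with insert columns materialized."""
        ins_points = sorted(self.insertions)
        out = []
        for rid, row in self.reference.rows + [(self.query_id, self.query_row)]:
            is_query = rid == self.query_id and row is self.query_row
            parts = []
            prev = 0
            for p in ins_points:
                parts.append(row[prev : p + 1])
                chunk = self.insertions[p]
                parts.append(chunk if is_query else GAP * len(chunk))
                prev = p + 1
            parts.append(row[prev:])
            out.append((rid, "".join(parts)))
        return out


class ReferenceDb:
    """Reference alignment with an anchor row and pocket definitions."""

    def __init__(self, alignment: SeedAlignment, reference_id: str, pockets: PocketMap):
        self.alignment = alignment
        self.reference_id = reference_id
        self.pockets = pockets
        ref_row = alignment.row(reference_id)  # KeyError if absent
        # map 1-based ungapped reference index -> alignment column
        self._index_to_column: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(ref_row):
            if ch != GAP and ch != ".":
                pos += 1
                self._index_to_column[pos] = col
        ref_len = pos
        for idx in list(pockets.P1) + list(pockets.P2):
            if idx > ref_len:
                raise ValueError(
                    f"pocket index {idx} beyond reference length {ref_len}"
                )
        self._profile: ProfileHmm | None = None

    def column_for(self, ref_index: int) -> int:
        return self._index_to_column[ref_index]

    @property
    def profile(self) -> ProfileHmm:
        """Profile over *all* reference columns (no gap trimming), cached."""
        if self._profile is None:
            self._profile = build_profile(
                self.alignment,
                gap_fraction_cutoff=1.0,
                pseudocount_weight=1.0,
                name="reference",
            )
        return self._profile

    def without(self, seq_id: str) -> "ReferenceDb":
        if seq_id == self.reference_id:
            raise ValueError("cannot remove the anchor row")
        return ReferenceDb(self.alignment.without(seq_id), self.reference_id, self.pockets)


def align_query(refdb: ReferenceDb, protein: str, query_id: str = "query") -> AugmentedAlignment:
    """Align a query to the reference alignment, preserving its columns.

    Uses profile-to-sequence Viterbi alignment: each query residue is
    assigned to a reference column (match) or recorded as an insertion;
    columns the query does not reach are gapped.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    profile = refdb.profile
    _, path = viterbi_align(profile, protein)
    n_cols = refdb.alignment.columns
    row = [GAP] * n_cols
    insertions: dict[int, list[str]] = {}
    col_of_state = profile.column_index
    for state, mi, ri in path:
        if state == "M":
            row[col_of_state[mi]] = protein[ri]
        elif state == "I":
            insertions.setdefault(col_of_state[mi], []).append(protein[ri])
    return AugmentedAlignment(
        reference=refdb.alignment,
        query_id=query_id,
        query_row="".join(row),
        insertions={k: "".join(v) for k, v in insertions.items()},
    )


def extract_active_site(
    refdb: ReferenceDb, augmented: AugmentedAlignment, protein_id: str | None = None
) -> ActiveSiteCall:
    """Read the query residues in the reference pocket columns ('-' if gapped)."""
    row = augmented.query_row
    cols = {"P1": [], "P2": []}
    residues = {"P1": [], "P2": []}
    for site, indices in (("P1", refdb.pockets.P1), ("P2", refdb.pockets.P2)):
        for idx in indices:
            col = refdb.column_for(idx)
            cols[site].append(col)
            residues[site].append(row[col])
    return ActiveSiteCall(
        protein_id=protein_id or augmented.query_id,
        P1_residues="".join(residues["P1"]),
        P2_residues="".join(residues["P2"]),
        aligned_columns=cols,
    )


def call_active_site(refdb: ReferenceDb, protein: str, protein_id: str = "query") -> ActiveSiteCall:
    """Convenience: align then extract."""
    aug = align_query(refdb, protein, query_id=protein_id)
    return extract_active_site(refdb, aug, protein_id)


def score_accuracy(
    predicted: list[ActiveSiteCall], truth: list[ActiveSiteCall]
) -> dict:
    """Fraction of correctly predicted pocket residues, with diagnostics.

    Returns overall accuracy across P1+P2 positions, per-position
    accuracies for each site, and an off-by-one tally: wrong positions
    whose predicted residue matches the truth at an adjacent pocket
    position (a signature of one-residue misalignment).
    """
    truth_by_id = {t.protein_id: t for t in truth}
    missing = [p.protein_id for p in predicted if p.protein_id not in truth_by_id]
    if missing:
        raise ValueError(f"no truth for ids: {missing}")
    n_p1 = len(predicted[0].P1_residues) if predicted else 0
    n_p2 = len(predicted[0].P2_residues) if predicted else 0
    per_pos = {"P1": [0] * n_p1, "P2": [0] * n_p2}
    off_by_one = 0
    correct = total = 0
    for pred in predicted:
        tr = truth_by_id[pred.protein_id]
        for site, pres, tres in (
            ("P1", pred.P1_residues, tr.P1_residues),
            ("P2", pred.P2_residues, tr.P2_residues),
        ):
            if len(pres) != len(tres):
                raise ValueError(f"{pred.protein_id}: pocket length mismatch at {site}")
            for i, (a, b) in enumerate(zip(pres, tres)):
                total += 1
                if a == b:
                    correct += 1
                    per_pos[site][i] += 1
                else:
                    neighbors = tres[max(0, i - 1) : i + 2]
                    if a != GAP and a in neighbors:
                        off_by_one += 1
    n = len(predicted)
    return {
        "overall": correct / total if total else 0.0,
        "per_position": {
            site: [c / n if n else 0.0 for c in counts] for site, counts in per_pos.items()
        },
        "off_by_one": off_by_one,
        "n_positions": total,
    }


def write_tsv(calls: list[ActiveSiteCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tP1\tP2\n")
        for c in calls:
            fh.write(f"{c.protein_id}\t{c.P1_residues}\t{c.P2_residues}\n")
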