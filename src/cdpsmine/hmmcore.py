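"""Profile hidden Markov models for protein family detection and classification.

A deliberately small plan7-style architecture: one match state per retained
alignment column, flanked insert and delete states, local (Smith-Waterman
style) Viterbi scoring in bits against a background residue distribution.
Entry into and exit from any match state is free, so scores are comparable
across differently truncated homologs.

Scoring uses best-path (Viterbi) rather than Forward so that every score is
exactly reproducible by brute-force path enumeration; detection cutoffs are
calibrated from seed self-scores rather than E-values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"

#: uniform background over the 20 standard residues
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

NEG_INF = float("-inf")


@dataclass
class SeedAlignment:
    """A seed multiple sequence alignment: rows of equal-length aligned strings."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, s in self.rows:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "").replace(".", "")

    def without(self, seq_id: str) -> "SeedAlignment":
        rows = [(i, s) for i, s in self.rows if i != seq_id]
        return SeedAlignment(rows)

    @classmethod
    def from_file(cls, path: str | Path, fmt: str = "fasta") -> "SeedAlignment":
        """Load an aligned FASTA or Stockholm file."""
        aln = AlignIO.read(str(path), fmt)
        return cls([(r.id, str(r.seq).upper().replace(".", GAP)) for r in aln])

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.rows:
                fh.write(f">{rid}\n{seq}\n")


@dataclass
class ProfileHmm:
    """A profile HMM over the 20 standard amino acids.

    ``match_emissions`` is (K, 20) of probabilities; transitions are
    per-state probability arrays; ``column_index`` maps each match state
    back to its source alignment column. All scoring is log2-odds against
    ``background`` (insert states emit the background, so they score 0
    bits per emitted residue).
    """

    name: str
    match_emissions: np.ndarray  # (K, 20)
    t_mm: np.ndarray  # (K,), M_k -> M_{k+1}; last entry unused
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    bitscore_cutoff: float = 0.0
    column_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission distributions must sum to 1")
        for t3 in ((self.t_mm, self.t_mi, self.t_md), (self.t_im, self.t_ii), (self.t_dm, self.t_dd)):
            total = sum(np.asarray(t) for t in t3)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError("transition distributions must sum to 1")
        self._prepare_scores()

    def _prepare_scores(self) -> None:
        with np.errstate(divide="ignore"):
            self._m_score = np.log2(self.match_emissions / self.background[None, :])
            self._l_mm = np.log2(self.t_mm)
            self._l_mi = np.log2(self.t_mi)
            self._l_md = np.log2(self.t_md)
            self._l_im = np.log2(self.t_im)
            self._l_ii = np.log2(self.t_ii)
            self._l_dm = np.log2(self.t_dm)
            self._l_dd = np.log2(self.t_dd)

    @property
    def n_states(self) -> int:
        return self.match_emissions.shape[0]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "name": self.name,
            "match_emissions": self.match_emissions.tolist(),
            "t_mm": self.t_mm.tolist(),
            "t_mi": self.t_mi.tolist(),
            "t_md": self.t_md.tolist(),
            "t_im": self.t_im.tolist(),
            "t_ii": self.t_ii.tolist(),
            "t_dm": self.t_dm.tolist(),
            "t_dd": self.t_dd.tolist(),
            "background": self.background.tolist(),
            "bitscore_cutoff": self.bitscore_cutoff,
            "column_index": list(self.column_index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHmm":
        return cls(
            name=d["name"],
            match_emissions=np.array(d["match_emissions"]),
            t_mm=np.array(d["t_mm"]),
            t_mi=np.array(d["t_mi"]),
            t_md=np.array(d["t_md"]),
            t_im=np.array(d["t_im"]),
            t_ii=np.array(d["t_ii"]),
            t_dm=np.array(d["t_dm"]),
            t_dd=np.array(d["t_dd"]),
            background=np.array(d["background"]),
            bitscore_cutoff=d["bitscore_cutoff"],
            column_index=list(d["column_index"]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "ProfileHmm":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class HmmHit:
    protein_id: str
    model: str
    bitscore: float
    envelope: tuple[int, int]  # 0-based half-open residue interval

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


@dataclass
class SubfamilyCall:
    label: str  # {NYH, XYP, SYQ, unclassified}
    per_model_bitscores: dict[str, float]


def _encode(protein: str) -> np.ndarray:
    """Encode a protein as residue indices; non-standard residues get -1."""
    return np.array([AA_INDEX.get(a, -1) for a in protein.upper()], dtype=int)


def build_profile(
    seed: SeedAlignment,
    gap_fraction_cutoff: float = 0.5,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
    background: np.ndarray | None = None,
) -> ProfileHmm:
    """Build a profile HMM from a seed alignment.

    Columns whose gap fraction exceeds ``gap_fraction_cutoff`` (and columns
    that are entirely gaps) are dropped; the survivors become match states.
    Match emissions are pseudocount-smoothed column frequencies; transition
    probabilities are counted from the implied match/insert/delete state
    paths of the seed rows, with one pseudo-observation per allowed move.
    Sequence weighting is uniform.
    """
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    n_rows = len(seed.rows)
    cols = seed.columns
    col_matrix = [[s[c] for _, s in seed.rows] for c in range(cols)]
    match_cols = []
    for c in range(cols):
        gaps = sum(1 for ch in col_matrix[c] if ch in (GAP, "."))
        gap_frac = gaps / n_rows
        if gap_frac >= 1.0:
            continue
        if gap_frac > gap_fraction_cutoff:
            continue
        match_cols.append(c)
    if not match_cols:
        raise ValueError(f"{name}: no alignment columns survive gap trimming")
    k = len(match_cols)

    emissions = np.zeros((k, 20))
    for mi, c in enumerate(match_cols):
        counts = np.zeros(20)
        for ch in col_matrix[c]:
            idx = AA_INDEX.get(ch, -1)
            if idx >= 0:
                counts[idx] += 1.0
        n_obs = counts.sum()
        emissions[mi] = (counts + pseudocount_weight * bg) / (n_obs + pseudocount_weight)

    # transition counts from the state path of each row
    c_mm = np.zeros(k)
    c_mi = np.zeros(k)
    c_md = np.zeros(k)
    c_im = np.zeros(k)
    c_ii = np.zeros(k)
    c_dm = np.zeros(k)
    c_dd = np.zeros(k)
    match_set = set(match_cols)
    for _, row in seed.rows:
        prev = None  # (state_char, match_index)
        pending_inserts = 0
        mi = -1
        for c, ch in enumerate(row):
            if c in match_set:
                mi += 1
                state = "M" if ch not in (GAP, ".") else "D"
                if prev is not None:
                    pstate, pmi = prev
                    if pending_inserts > 0:
                        if pstate == "M":
                            c_mi[pmi] += 1
                        c_ii[pmi] += pending_inserts - 1
                        c_im[pmi] += 1 if state == "M" else 0
                        # insert->delete not modeled; count as insert->match
                        if state == "D":
                            c_im[pmi] += 1
                    else:
                        if pstate == "M" and state == "M":
                            c_mm[pmi] += 1
                        elif pstate == "M" and state == "D":
                            c_md[pmi] += 1
                        elif pstate == "D" and state == "M":
                            c_dm[pmi] += 1
                        elif pstate == "D" and state == "D":
                            c_dd[pmi] += 1
                prev = (state, mi)
                pending_inserts = 0
            else:
                if ch not in (GAP, ".") and prev is not None:
                    pending_inserts += 1

    # smooth with one pseudo-observation per allowed move and normalize
    def _norm(*counts: np.ndarray) -> list[np.ndarray]:
        stacked = [c + 1.0 for c in counts]
        total = sum(stacked)
        return [c / total for c in stacked]

    t_mm, t_mi, t_md = _norm(c_mm, c_mi, c_md)
    t_im, t_ii = _norm(c_im, c_ii)
    t_dm, t_dd = _norm(c_dm, c_dd)

    return ProfileHmm(
        name=name,
        match_emissions=emissions,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        background=bg,
        column_index=match_cols,
    )


def score_protein(hmm: ProfileHmm, protein: str) -> float:
    """Local Viterbi bitscore of ``protein`` under ``hmm``.

    Non-standard residues (X etc.) are scored as background (0 bits) in
    match states. Returns 0.0 when no positive-scoring alignment exists
    (the empty alignment is always available in local mode).
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    enc = _encode(protein)
    k = hmm.n_states
    m_score = hmm._m_score

    # emission score rows; unknown residues score 0 everywhere
    best = 0.0
    v_m = np.full(k, NEG_INF)
    v_i = np.full(k, NEG_INF)
    v_d = np.full(k, NEG_INF)
    l_mm, l_mi, l_md = hmm._l_mm, hmm._l_mi, hmm._l_md
    l_im, l_ii = hmm._l_im, hmm._l_ii
    l_dm, l_dd = hmm._l_dm, hmm._l_dd

    for idx in enc:
        emit = m_score[:, idx] if idx >= 0 else np.zeros(k)
        new_m = np.full(k, 0.0)  # free local entry into any match state
        from_m = np.concatenate(([NEG_INF], v_m[:-1] + l_mm[:-1]))
        from_i = np.concatenate(([NEG_INF], v_i[:-1] + l_im[:-1]))
        from_d = np.concatenate(([NEG_INF], v_d[:-1] + l_dm[:-1]))
        new_m = np.maximum(new_m, np.maximum(from_m, np.maximum(from_i, from_d)))
        new_m = new_m + emit
        new_i = np.maximum(v_m + l_mi, v_i + l_ii)
        # deletes consume no residue: computed within the new row via a
        # prefix-max over (new_m[j] + t_md[j] + sum of t_dd up to k)
        cum_dd = np.concatenate(([0.0], np.cumsum(l_dd[:-1])))
        cand = new_m + l_md - np.concatenate((cum_dd[1:], [np.inf]))
        run = np.maximum.accumulate(np.concatenate(([NEG_INF], cand[:-1])))
        new_d = run + cum_dd
        v_m, v_i, v_d = new_m, new_i, new_d
        row_best = float(v_m.max())
        if row_best > best:
            best = row_best
    return best


def viterbi_align(hmm: ProfileHmm, protein: str) -> tuple[float, list[tuple[str, int, int]]]:
    """Local Viterbi with traceback.

    Returns ``(bitscore, path)`` where path is a list of
    ``(state, match_index, residue_index)`` triples; ``state`` is one of
    'M', 'I', 'D'; residue_index is -1 for deletes. Pure-Python DP —
    use :func:`score_protein` when only the score is needed.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    enc = _encode(protein)
    n, k = len(enc), hmm.n_states
    m_score = hmm._m_score
    l_mm, l_mi, l_md = hmm._l_mm, hmm._l_mi, hmm._l_md
    l_im, l_ii = hmm._l_im, hmm._l_ii
    l_dm, l_dd = hmm._l_dm, hmm._l_dd

    vm = [[NEG_INF] * k for _ in range(n)]
    vi = [[NEG_INF] * k for _ in range(n)]
    vd = [[NEG_INF] * k for _ in range(n)]
    pm: list[list[tuple]] = [[None] * k for _ in range(n)]
    pi: list[list[tuple]] = [[None] * k for _ in range(n)]
    pd: list[list[tuple]] = [[None] * k for _ in range(n)]

    best, best_cell = 0.0, None
    for i in range(n):
        idx = enc[i]
        for j in range(k):
            emit = m_score[j][idx] if idx >= 0 else 0.0
            cands = [(0.0, None)]
            if i > 0 and j > 0:
                cands.append((vm[i - 1][j - 1] + l_mm[j - 1], ("M", i - 1, j - 1)))
                cands.append((vi[i - 1][j - 1] + l_im[j - 1], ("I", i - 1, j - 1)))
                cands.append((vd[i - 1][j - 1] + l_dm[j - 1], ("D", i - 1, j - 1)))
            val, ptr = max(cands, key=lambda t: t[0])
            vm[i][j] = val + emit
            pm[i][j] = ptr
            if i > 0:
                cands_i = [
                    (vm[i - 1][j] + l_mi[j], ("M", i - 1, j)),
                    (vi[i - 1][j] + l_ii[j], ("I", i - 1, j)),
                ]
                vi[i][j], pi[i][j] = max(cands_i, key=lambda t: t[0])
            if j > 0:
                cands_d = [
                    (vm[i][j - 1] + l_md[j - 1], ("M", i, j - 1)),
                    (vd[i][j - 1] + l_dd[j - 1], ("D", i, j - 1)),
                ]
                vd[i][j], pd[i][j] = max(cands_d, key=lambda t: t[0])
            if vm[i][j] > best:
                best, best_cell = vm[i][j], ("M", i, j)

    path: list[tuple[str, int, int]] = []
    cell = best_cell
    tables = {"M": (vm, pm), "I": (vi, pi), "D": (vd, pd)}
    while cell is not None:
        state, i, j = cell
        path.append((state, j, i if state != "D" else -1))
        cell = tables[state][1][i][j]
    path.reverse()
    return best, path


def set_cutoff_from_seeds(
    hmm: ProfileHmm, seeds: Iterable[str], margin_bits: float = 10.0
) -> ProfileHmm:
    """Set the detection cutoff to (min seed self-score - margin)."""
    scores = [score_protein(hmm, s) for s in seeds]
    if not scores:
        raise ValueError("seeds must be non-empty")
    hmm.bitscore_cutoff = min(scores) - margin_bits
    return hmm


def detect(hmm: ProfileHmm, proteins: Sequence) -> list[HmmHit]:
    """Return hits for all proteins scoring at or above the model cutoff.

    ``proteins`` is a sequence of objects with ``id`` and ``sequence``
    attributes (or ``(id, sequence)`` tuples). Hits are sorted by
    descending bitscore.
    """
    hits = []
    for p in proteins:
        pid, seq = (p.id, p.sequence) if hasattr(p, "id") else p
        score = score_protein(hmm, seq)
        if score >= hmm.bitscore_cutoff:
            _, path = viterbi_align(hmm, seq)
            residues = [r for s, _, r in path if s in ("M", "I") and r >= 0]
            env = (min(residues), max(residues) + 1) if residues else (0, 0)
            hits.append(HmmHit(protein_id=pid, model=hmm.name, bitscore=score, envelope=env))
    hits.sort(key=lambda h: (-h.bitscore, h.protein_id))
    return hits


# fixed priority order for subfamily tie-breaking
SUBFAMILY_ORDER = ("NYH", "XYP", "SYQ")


def classify_subfamily(models: Sequence[ProfileHmm], protein: str) -> SubfamilyCall:
    """Classify a protein by competing subfamily models.

    The label is the model with the highest bitscore among those above
    their own cutoffs; exact ties break by the fixed order NYH > XYP > SYQ
    (then model name); 'unclassified' when no model passes.
    """
    if not models:
        raise ValueError("at least one model required")
    scores = {m.name: score_protein(m, protein) for m in models}
    passing = [m for m in models if scores[m.name] >= m.bitscore_cutoff]
    if not passing:
        return SubfamilyCall(label="unclassified", per_model_bitscores=scores)

    def priority(m: ProfileHmm) -> tuple:
        rank = SUBFAMILY_ORDER.index(m.name) if m.name in SUBFAMILY_ORDER else len(SUBFAMILY_ORDER)
        return (-scores[m.name], rank, m.name)

    winner = min(passing, key=priority)
    return SubfamilyCall(label=winner.name, per_model_bitscores=scores)


def read_hmmer3(path: str | Path) -> ProfileHmm:
    """Minimal read-only import of a HMMER3 text-format .hmm file.

    Only match emissions, transitions and the background-equivalent null
    are recovered; scores from imported models are comparable within the
    model but not calibrated against HMMER's own bitscores.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    name = "imported"
    k = 0
    i = 0
    while i < len(lines) and not lines[i].startswith("HMM "):
        if lines[i].startswith("NAME"):
            name = lines[i].split()[1]
        if lines[i].startswith("LENG"):
            k = int(lines[i].split()[1])
        i += 1
    if k == 0:
        raise ValueError(f"{path}: not a HMMER3 file (no LENG)")
    order = lines[i].split()[1:21]  # amino-acid column order
    i += 2  # skip transition header line
    # optional COMPO line
    if lines[i].strip().startswith("COMPO"):
        i += 3
    else:
        i += 2  # insert0 emissions + begin transitions
    emissions = np.zeros((k, 20))
    t = {key: np.full(k, 1.0 / 3) for key in ("mm", "mi", "md")}
    t_im = np.full(k, 0.5)
    t_ii = np.full(k, 0.5)
    t_dm = np.full(k, 0.5)
    t_dd = np.full(k, 0.5)
    row = 0
    while i < len(lines) and row < k:
        parts = lines[i].split()
        vals = [math.exp(-float(x)) if x != "*" else 0.0 for x in parts[1:21]]
        for aa, v in zip(order, vals):
            if aa in AA_INDEX:
                emissions[row][AA_INDEX[aa]] = v
        trans = lines[i + 2].split()
        tv = [math.exp(-float(x)) if x != "*" else 0.0 for x in trans[:7]]
        t["mm"][row], t["mi"][row], t["md"][row] = tv[0], tv[1], tv[2]
        t_im[row], t_ii[row] = tv[3], tv[4]
        t_dm[row], t_dd[row] = tv[5], tv[6]
        row += 1
        i += 3
    emissions = emissions / emissions.sum(axis=1, keepdims=True)

    def _renorm(*arrs):
        total = sum(arrs)
        total[total == 0] = 1.0
        return [a / total for a in arrs]

    t_mm, t_mi, t_md = _renorm(t["mm"], t["mi"], t["md"])
    t_im, t_ii = _renorm(t_im, t_ii)
    t_dm, t_dd = _renorm(t_dm, t_dd)
    return ProfileHmm(
        name=name,
        match_emissions=emissions,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        column_index=list(range(k)),
    )
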