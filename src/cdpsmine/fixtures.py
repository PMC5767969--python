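"""Deterministic synthetic fixtures with machine-readable truth.

Generates planted-motif protein families (with subfamily triads, pocket
signatures and substrate labels), labeled substrate training tables,
domain seed families, and synthetic genomes embedding gene clusters —
everything needed to exercise the pipeline end to end without downloads.
All generation is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hmmcore import AMINO_ACIDS, SeedAlignment
from .seqio import GenomeRecord, OrfCall
from .substrate import TrainingSet

#: most-frequent E. coli codon per amino acid (fixed for determinism)
CODON_TABLE = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "E": "GAA", "Q": "CAG", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}
STOP_CODON = "TAA"

#: spacer pattern free of start codons (ATG/GTG/TTG) at every offset on
#: both strands, with stop codons in all three forward frames (period 4 is
#: coprime to 3, so the TAA lands in every frame within 12 bases)
SPACER_UNIT = "TAAG"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def spacer(length: int) -> str:
    return (SPACER_UNIT * (length // len(SPACER_UNIT) + 2))[:length]


def back_translate(protein: str) -> str:
    """Deterministic back-translation using the fixed codon table."""
    return "".join(CODON_TABLE[aa] for aa in protein)


def gene_sequence(protein: str) -> str:
    """A plantable gene: ATG + codons + stop (translates to 'M' + protein)."""
    return "ATG" + back_translate(protein) + STOP_CODON


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a planted-motif synthetic protein family."""

    length: int = 240
    subfamily_sizes: tuple[tuple[str, int], ...] = (("NYH", 10), ("XYP", 9), ("SYQ", 1))
    # first three positions carry the namesake triad; the rest model the
    # broader phylogenetic divergence between subfamilies
    subfamily_motifs: tuple[tuple[str, str], ...] = (
        ("NYH", "NYH" + "WGKDERAMT"),
        ("XYP", "LYP" + "FASNQHCVG"),
        ("SYQ", "SYQ" + "YTPEDKLIW"),
    )
    motif_positions: tuple[int, ...] = (60, 61, 62, 20, 30, 40, 50, 70, 80, 140, 200, 210)
    mutation_rate: float = 0.03
    pocket_p1: tuple[int, ...] = (90, 95, 100, 105, 110, 115, 120, 125)
    pocket_p2: tuple[int, ...] = (150, 155, 160, 165, 170, 175, 180, 185)
    substrate_classes: tuple[str, ...] = tuple("LFWYAVDEKRST")
    seed: int = 0

    def __post_init__(self) -> None:
        special = set(self.motif_positions) | set(self.pocket_p1) | set(self.pocket_p2)
        if len(special) != len(self.motif_positions) + len(self.pocket_p1) + len(self.pocket_p2):
            raise ValueError("motif and pocket positions must not overlap")
        if max(special) >= self.length:
            raise ValueError("motif/pocket positions beyond sequence length")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation rate must be in [0, 0.5]")


@dataclass
class SeqTruth:
    """Ground truth for one generated family member."""

    id: str
    subfamily: str
    sequence: str
    p1_residues: str
    p2_residues: str
    substrate_p1: str
    substrate_p2: str


def pocket_signatures(
    classes: tuple[str, ...], n_positions: int, seed: int
) -> dict[str, str]:
    """A deterministic, pairwise-distinct pocket signature per class."""
    rng = np.random.default_rng(seed)
    sigs: dict[str, str] = {}
    used: set[str] = set()
    for c in classes:
        while True:
            sig = _random_protein(rng, n_positions)
            if sig not in used:
                used.add(sig)
                sigs[c] = sig
                break
    return sigs


def gen_family(spec: FamilySpec) -> tuple[list[tuple[str, str]], dict[str, SeqTruth]]:
    """Generate the family: consensus + i.i.d. substitutions, then motifs
    and pocket signatures re-imposed. Same spec => byte-identical output."""
    rng = np.random.default_rng(spec.seed)
    consensus = _random_protein(rng, spec.length)
    motifs = dict(spec.subfamily_motifs)
    sig_p1 = pocket_signatures(spec.substrate_classes, len(spec.pocket_p1), spec.seed + 1)
    sig_p2 = pocket_signatures(spec.substrate_classes, len(spec.pocket_p2), spec.seed + 2)
    aa_list = list(AMINO_ACIDS)

    sequences: list[tuple[str, str]] = []
    truth: dict[str, SeqTruth] = {}
    counter = 0
    for subfamily, size in spec.subfamily_sizes:
        motif = motifs[subfamily]
        if len(motif) != len(spec.motif_positions):
            raise ValueError(f"motif {motif!r} does not fit motif positions")
        for _ in range(size):
            seq = list(consensus)
            mutate = rng.random(spec.length) < spec.mutation_rate
            for pos in np.flatnonzero(mutate):
                seq[pos] = aa_list[rng.integers(20)]
            for pos, res in zip(spec.motif_positions, motif):
                seq[pos] = res
            s1 = spec.substrate_classes[rng.integers(len(spec.substrate_classes))]
            s2 = spec.substrate_classes[rng.integers(len(spec.substrate_classes))]
            for pos, res in zip(spec.pocket_p1, sig_p1[s1]):
                seq[pos] = res
            for pos, res in zip(spec.pocket_p2, sig_p2[s2]):
                seq[pos] = res
            sid = f"{subfamily}_{counter:03d}"
            counter += 1
            seq_str = "".join(seq)
            sequences.append((sid, seq_str))
            truth[sid] = SeqTruth(
                id=sid,
                subfamily=subfamily,
                sequence=seq_str,
                p1_residues=sig_p1[s1],
                p2_residues=sig_p2[s2],
                substrate_p1=s1,
                substrate_p2=s2,
            )
    return sequences, truth


def family_alignment(sequences: list[tuple[str, str]]) -> SeedAlignment:
    """Generated families are ungapped and equal-length: the trivial MSA."""
    return SeedAlignment(list(sequences))


def gen_training(
    spec: FamilySpec,
    site: str,
    n_per_class: int = 5,
    label_noise: float = 0.0,
    vector_noise: float = 0.0,
    seed: int | None = None,
) -> TrainingSet:
    """A labeled pocket-residue training table around the class signatures.

    ``label_noise`` permutes that fraction of labels among themselves;
    ``vector_noise`` is a per-position substitution probability.
    """
    if site not in ("P1", "P2"):
        raise ValueError("site must be P1 or P2")
    positions = spec.pocket_p1 if site == "P1" else spec.pocket_p2
    sig_seed = spec.seed + (1 if site == "P1" else 2)
    sigs = pocket_signatures(spec.substrate_classes, len(positions), sig_seed)
    rng = np.random.default_rng(spec.seed + 10 if seed is None else seed)
    aa_list = list(AMINO_ACIDS)
    examples: list[tuple[str, str]] = []
    for c in spec.substrate_classes:
        for _ in range(n_per_class):
            vec = list(sigs[c])
            for i in range(len(vec)):
                if rng.random() < vector_noise:
                    vec[i] = aa_list[rng.integers(20)]
            examples.append(("".join(vec), c))
    if label_noise > 0:
        n = len(examples)
        n_noisy = int(round(label_noise * n))
        idx = rng.choice(n, size=n_noisy, replace=False)
        perm = rng.permutation(idx)
        labels = [label for _, label in examples]
        new_labels = list(labels)
        for src, dst in zip(idx, perm):
            new_labels[dst] = labels[src]
        examples = [(v, new_labels[i]) for i, (v, _) in enumerate(examples)]
    return TrainingSet(site=site, examples=examples)


def gen_domain_seed(
    name: str, seed: int, n_sequences: int = 8, length: int = 150, mutation_rate: float = 0.03
) -> SeedAlignment:
    """A synthetic ungapped seed family for one tailoring/resistance domain."""
    rng = np.random.default_rng(seed)
    consensus = _random_protein(rng, length)
    aa_list = list(AMINO_ACIDS)
    rows = []
    for i in range(n_sequences):
        seq = list(consensus)
        mutate = rng.random(length) < mutation_rate
        for pos in np.flatnonzero(mutate):
            seq[pos] = aa_list[rng.integers(20)]
        rows.append((f"{name}_{i}", "".join(seq)))
    return SeedAlignment(rows)


# ---------------------------------------------------------------------------
# synthetic genomes


@dataclass(frozen=True)
class ClusterLayout:
    """One planted gene cluster: CDPS member ids plus tailoring domains."""

    cdps_ids: tuple[str, ...]
    tailoring: tuple[str, ...] = ()
    cdps_spacing_bp: int = 2000
    tailoring_spacing_bp: int = 500


@dataclass(frozen=True)
class SyntheticSurveySpec:
    layouts: tuple[ClusterLayout, ...]
    n_genomes: int
    duplicate_fraction: float = 0.0
    flank_bp: int = 1000
    window_bp: int = 2500
    seed: int = 0


@dataclass
class GenomeTruth:
    genome_id: str
    duplicate_of: str | None
    clusters: list[dict] = field(default_factory=list)
    orfs: list[OrfCall] = field(default_factory=list)


def gen_genomes(
    spec: SyntheticSurveySpec,
    family_sequences: dict[str, str],
    domain_seeds: dict[str, SeedAlignment],
) -> tuple[list[GenomeRecord], dict[str, GenomeTruth]]:
    """Emit synthetic genomes embedding the planted clusters.

    ``family_sequences`` maps CDPS id -> protein; ``domain_seeds`` maps
    domain name -> seed alignment (the first row is the planted copy).
    Spacers contain no start codons at any offset, so the planted genes
    are exactly the ORFs an internal six-frame caller recovers at a
    suitable min_aa. Truth tables carry every planted ORF and cluster.
    """
    n_unique = max(1, int(round(spec.n_genomes * (1.0 - spec.duplicate_fraction))))
    genomes: list[GenomeRecord] = []
    truth: dict[str, GenomeTruth] = {}
    originals: list[GenomeRecord] = []
    for i in range(spec.n_genomes):
        gid = f"genome_{i:03d}"
        if i >= n_unique:
            src = originals[(i - n_unique) % len(originals)]
            genomes.append(GenomeRecord(id=gid, sequence=src.sequence, source="duplicate"))
            src_truth = truth[src.id]
            truth[gid] = GenomeTruth(
                genome_id=gid,
                duplicate_of=src.id,
                clusters=[
                    {
                        **c,
                        "genome_id": gid,
                        "cdps_orf_ids": [
                            oid.replace(src.id, gid, 1) for oid in c["cdps_orf_ids"]
                        ],
                    }
                    for c in src_truth.clusters
                ],
                orfs=[replace(o, contig_id=gid, id="") for o in src_truth.orfs],
            )
            continue
        layout = spec.layouts[i % len(spec.layouts)]
        parts: list[str] = [spacer(spec.flank_bp)]
        pos = spec.flank_bp
        orfs: list[OrfCall] = []
        kinds: list[str] = []
        genes: list[tuple[str, str, int]] = []  # (kind, protein, spacing_after)
        for j, cid in enumerate(layout.cdps_ids):
            spacing = (
                layout.cdps_spacing_bp
                if j < len(layout.cdps_ids) - 1
                else layout.tailoring_spacing_bp
            )
            genes.append((f"cdps:{cid}", family_sequences[cid], spacing))
        for dom in layout.tailoring:
            genes.append(
                (
                    f"domain:{dom}",
                    domain_seeds[dom].rows[0][1].replace("-", ""),
                    layout.tailoring_spacing_bp,
                )
            )
        for kind, protein, spacing_after in genes:
            dna = gene_sequence(protein)
            call = OrfCall(
                contig_id=gid,
                start=pos,
                end=pos + len(dna),
                strand="+",
                protein="M" + protein,
                caller="internal",
            )
            orfs.append(call)
            kinds.append(kind)
            parts.append(dna)
            parts.append(spacer(spacing_after))
            pos += len(dna) + spacing_after
        parts.append(spacer(spec.flank_bp))
        genome = GenomeRecord(id=gid, sequence="".join(parts), source="synthetic")
        genomes.append(genome)
        originals.append(genome)
        truth[gid] = GenomeTruth(
            genome_id=gid,
            duplicate_of=None,
            clusters=_expected_clusters(gid, orfs, kinds, spec.window_bp),
            orfs=orfs,
        )
    return genomes, truth


def _expected_clusters(
    gid: str, orfs: list[OrfCall], kinds: list[str], window_bp: int
) -> list[dict]:
    """Truth clusters from planted geometry: CDPS windows merge when they
    overlap; domain genes belong to the cluster window they overlap."""
    cdps = [(o, k.split(":", 1)[1]) for o, k in zip(orfs, kinds) if k.startswith("cdps:")]
    groups: list[list[tuple[OrfCall, str]]] = []
    cur: list[tuple[OrfCall, str]] = []
    cur_end = -1
    for orf, cid in sorted(cdps, key=lambda t: t[0].start):
        if cur and orf.start - window_bp <= cur_end:
            cur.append((orf, cid))
            cur_end = max(cur_end, orf.end + window_bp)
        else:
            if cur:
                groups.append(cur)
            cur = [(orf, cid)]
            cur_end = orf.end + window_bp
    if cur:
        groups.append(cur)
    clusters = []
    for group in groups:
        w_start = max(0, min(o.start for o, _ in group) - window_bp)
        w_end = max(o.end for o, _ in group) + window_bp
        domains = sorted(
            k.split(":", 1)[1]
            for o, k in zip(orfs, kinds)
            if k.startswith("domain:") and o.start < w_end and o.end > w_start
        )
        clusters.append(
            {
                "genome_id": gid,
                "cdps_ids": [cid for _, cid in group],
                "cdps_orf_ids": [o.id for o, _ in group],
                "domains": domains,
                "window": [w_start, w_end],
            }
        )
    return clusters
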