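"""Cyclodipeptide structure prediction and fingerprint scoring.

Builds the 2,5-diketopiperazine (DKP) scaffold for a pair of amino-acid
substrates, applies tailoring reactions implied by annotated cluster
domains — enumerating all placements when the reaction site is ambiguous —
and scores predicted structures against known compounds with ECFP6-style
circular fingerprints and the Tanimoto coefficient.

Reaction semantics are deliberately coarse, curator-editable defaults:
each rule is a SMARTS rewrite (or a small bond-forming routine for the
aryl-aryl coupling) registered in ``DEFAULT_REACTIONS``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

AROMATIC_AA = set("FWYH")

#: side-chain fragments attached to the alpha carbon (beta atom first);
#: glycine and proline are handled structurally in :func:`build_dkp`
SIDE_CHAINS: dict[str, str] = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC",
    "K": "CCCCN",
    "L": "CC(C)C",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "[C@H](O)C",
    "V": "C(C)C",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
}

STANDARD_AA = set(SIDE_CHAINS) | {"G", "P"}


def canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def build_dkp(aa1: str, aa2: str, stereo: bool = True) -> str:
    """Canonical SMILES of the cyclo(aa1-aa2) 2,5-diketopiperazine.

    L,L stereochemistry by default; symmetric in its arguments (the
    canonicalizer maps cyclo(A-B) and cyclo(B-A) to the same string).
    """
    for aa in (aa1, aa2):
        if aa not in STANDARD_AA:
            raise ValueError(f"unknown residue {aa!r}")
    chains = SIDE_CHAINS if stereo else {k: _strip_stereo(v) for k, v in SIDE_CHAINS.items()}
    u1 = _residue_unit_with(aa1, True, stereo, chains)
    u2 = _residue_unit_with(aa2, False, stereo, chains)
    # DKP ring uses closure digit 8, proline rings digit 9; side-chain
    # fragments may freely use 1 and 2
    smiles = f"{u1}C(=O){u2}C8=O"
    return canonical(smiles)


def _strip_stereo(frag: str) -> str:
    return frag.replace("[C@@H]", "C").replace("[C@H]", "C")


def _residue_unit_with(aa: str, ring_open: bool, stereo: bool, chains: dict[str, str]) -> str:
    n = "N8" if ring_open else "N"
    ca = "[C@@H]" if stereo else "C"
    if aa == "G":
        return f"{n}C"
    if aa == "P":
        # written C-before-N around the fused CA, so the descriptor flips
        pro_ca = "[C@H]" if stereo else "C"
        return f"{n}9CCC{pro_ca}9"
    return f"{n}{ca}({chains[aa]})"


# ---------------------------------------------------------------------------
# tailoring reactions


def _apply_smarts_once(mol: Chem.Mol, rxn_smarts: str) -> list[Chem.Mol]:
    """All distinct single-site applications of a reaction SMARTS."""
    rxn = AllChem.ReactionFromSmarts(rxn_smarts)
    out = []
    for prods in rxn.RunReactants((mol,)):
        for p in prods:
            try:
                Chem.SanitizeMol(p)
                Chem.AssignStereochemistry(p, cleanIt=True, force=True)
            except Exception as exc:  # invalid chemistry: drop the variant
                logger.warning("dropping invalid tailoring product: %s", exc)
                continue
            out.append(p)
    return out


def _aryl_coupling(mol: Chem.Mol) -> list[Chem.Mol]:
    """Intramolecular C-C bond between aromatic CH carbons ortho to a
    phenol OH, one from each of two different rings (CYP121-style)."""
    patt = Chem.MolFromSmarts("[cH1:1][c]([OX2H])")
    matches = mol.GetSubstructMatches(patt)
    ring_info = mol.GetRingInfo()

    def ring_id(atom_idx: int) -> int:
        for i, ring in enumerate(ring_info.AtomRings()):
            if atom_idx in ring:
                return i
        return -1

    out = []
    sites = [m[0] for m in matches]
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            if ring_id(a) == ring_id(b):
                continue
            if mol.GetBondBetweenAtoms(a, b) is not None:
                continue
            rw = Chem.RWMol(mol)
            rw.AddBond(a, b, Chem.BondType.SINGLE)
            rw.GetAtomWithIdx(a).SetNumExplicitHs(0)
            rw.GetAtomWithIdx(b).SetNumExplicitHs(0)
            try:
                p = rw.GetMol()
                Chem.SanitizeMol(p)
            except Exception as exc:
                logger.warning("dropping invalid coupling product: %s", exc)
                continue
            out.append(p)
    return out


@dataclass
class TailoringReaction:
    """A domain-triggered structure transform.

    ``steps`` are reaction SMARTS (single-site applications, enumerated
    combinatorially) or a callable ``mol -> [product mols]``.
    ``applicability`` is a predicate on the (aa1, aa2) substrate pair.
    """

    name: str
    required_domain: str
    steps: Sequence[str | Callable]
    applicability: Callable[[str, str], bool] = lambda a, b: True
    site_ambiguous: bool = False

    def expand(self, mol: Chem.Mol) -> list[Chem.Mol]:
        out = []
        for step in self.steps:
            if callable(step):
                out.extend(step(mol))
            else:
                out.extend(_apply_smarts_once(mol, step))
        return out


#: alpha,beta-dehydrogenation at a ring alpha carbon with a substituted
#: beta; one variant per beta H count so product hydrogens are explicit
_DEHYDRO_H2 = "[CX4;H1;R:1]([NX3;R:2])[CX4;H2:3]>>[CH0:1]([N:2])=[CH1:3]"
_DEHYDRO_H1 = "[CX4;H1;R:1]([NX3;R:2])[CX4;H1:3]>>[CH0:1]([N:2])=[CH0:3]"
_DEHYDRO_H3 = "[CX4;H1;R:1]([NX3;R:2])[CX4;H3:3]>>[CH0:1]([N:2])=[CH2:3]"
#: ring amide N-H -> N-OH
_N_OXIDATION = "[NX3;H1;R:1]>>[N:1][OX2H1]"
#: hydroxyl/enol O-methylation (O on carbon)
_O_METHYLATION = "[OX2H1;$([OX2H1][#6]):1]>>[O:1]C"
#: ring amide N-methylation
_N_METHYLATION = "[NX3;H1;R:1]>>[N:1]C"
#: amide C=O,N-H -> C(OMe)=N (O-methylation with tautomerization)
_AMIDE_O_METHYLATION = "[C;R:1](=[O:2])[NX3;H1;R:3]>>[C:1]([O:2]C)=[N:3]"


def _both_aromatic(a: str, b: str) -> bool:
    return a in AROMATIC_AA and b in AROMATIC_AA


DEFAULT_REACTIONS: list[TailoringReaction] = [
    TailoringReaction(
        name="aryl_cc_coupling",
        required_domain="CYP121",
        steps=[_aryl_coupling],
        applicability=_both_aromatic,
        site_ambiguous=True,
    ),
    TailoringReaction(
        name="ring_n_oxidation",
        required_domain="N-oxygenase",
        steps=[_N_OXIDATION],
        site_ambiguous=True,
    ),
    TailoringReaction(
        name="alpha_beta_dehydrogenation",
        required_domain="AlbA",
        steps=[_DEHYDRO_H2, _DEHYDRO_H1, _DEHYDRO_H3],
        site_ambiguous=True,
    ),
    TailoringReaction(
        name="o_methylation",
        required_domain="Ndas_1149",
        steps=[_O_METHYLATION],
        site_ambiguous=True,
    ),
    TailoringReaction(
        name="ring_n_methylation",
        required_domain="Amir_4628",
        steps=[_N_METHYLATION],
        site_ambiguous=True,
    ),
    TailoringReaction(
        name="amide_on_methylation",
        required_domain="Ndas_1145",
        steps=[_N_METHYLATION, _AMIDE_O_METHYLATION],
        site_ambiguous=True,
    ),
]


@dataclass
class CompoundLibrary:
    """Predicted structures for one cluster: canonical SMILES plus the
    ordered list of reactions that produced each member."""

    cluster_id: str
    smiles: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("compound library must be non-empty")
        if len(set(self.smiles)) != len(self.smiles):
            raise ValueError("library SMILES must be distinct")


def apply_tailoring(
    scaffold: str,
    domains: Iterable[str],
    reactions: Sequence[TailoringReaction] | None = None,
    substrates: tuple[str, str] | None = None,
    cluster_id: str = "cluster",
    cap: int = 64,
) -> CompoundLibrary:
    """Apply every applicable tailoring reaction to the scaffold.

    All single- and multi-site application combinations are enumerated
    (combinatorial library), deduplicated on canonical SMILES, capped at
    ``cap`` members in lexicographic order. When no reaction applies the
    library is just the untailored scaffold.
    """
    reactions = DEFAULT_REACTIONS if reactions is None else reactions
    domain_set = set(domains)
    scaffold_canon = canonical(scaffold)
    applicable = [
        r
        for r in sorted(reactions, key=lambda r: r.name)
        if r.required_domain in domain_set
        and (substrates is None or r.applicability(*substrates))
    ]
    provenance: dict[str, list[str]] = {scaffold_canon: []}
    pool = {scaffold_canon}
    for rxn in applicable:
        # closure of the current pool under single applications of rxn
        frontier = set(pool)
        rounds = 0
        while frontier and rounds < 8:
            new: set[str] = set()
            for smi in sorted(frontier):
                mol = Chem.MolFromSmiles(smi)
                for prod in rxn.expand(mol):
                    p = Chem.MolToSmiles(prod)
                    if p not in pool and p not in new:
                        new.add(p)
                        provenance[p] = provenance.get(smi, []) + [rxn.name]
            pool |= new
            frontier = new
            rounds += 1
    tailored = sorted(pool - {scaffold_canon})
    members = tailored if tailored else [scaffold_canon]
    members = members[:cap]
    return CompoundLibrary(
        cluster_id=cluster_id,
        smiles=members,
        provenance={s: provenance.get(s, []) for s in members},
    )


# ---------------------------------------------------------------------------
# fingerprints

_FP_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)


@dataclass(frozen=True)
class Fingerprint:
    """ECFP6-equivalent circular fingerprint: radius 3, 2048 bits."""

    bits: frozenset[int]

    @property
    def n_bits(self) -> int:
        return len(self.bits)


def fingerprint(smiles: str) -> Fingerprint:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    bv = _FP_GENERATOR.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B|; defined as 0 (with a warning) for two empty sets."""
    union = a.bits | b.bits
    if not union:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0")
        return 0.0
    return len(a.bits & b.bits) / len(union)


def score_prediction(library: CompoundLibrary, truth: str) -> dict[str, float]:
    """Median and max Tanimoto of the truth against every library member."""
    truth_fp = fingerprint(truth)
    scores = [tanimoto(fingerprint(s), truth_fp) for s in library.smiles]
    return {"median_tanimoto": float(median(scores)), "max_tanimoto": max(scores)}


def mean_median_tanimoto(scored: Iterable[dict[str, float]]) -> float:
    """Batch aggregator: mean of per-cluster median Tanimoto coefficients."""
    medians = [s["median_tanimoto"] for s in scored]
    if not medians:
        raise ValueError("no scored clusters")
    return sum(medians) / len(medians)
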