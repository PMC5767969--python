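"""Gene cluster assembly and domain annotation around detected CDPSs.

Each CDPS hit seeds a window of +-window_bp nucleotides around its ORF;
overlapping windows on the same contig merge into one cluster (so two
CDPSs closer than the window width share a cluster). Every ORF overlapping
the merged window becomes a cluster member and is scored against a library
of domain HMMs; the best-scoring domain above its cutoff is the primary
annotation, all passing hits are logged, and unmatched ORFs are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hmmcore import HmmHit, ProfileHmm, SeedAlignment, build_profile, score_protein, set_cutoff_from_seeds
from .seqio import OrfCall

DEFAULT_WINDOW_BP = 2500

DOMAIN_CATEGORIES = ("cdps_tailoring", "generic_tailoring", "resistance", "other")

#: the six cyclodipeptide-specific tailoring domains and their reaction names
CDPS_TAILORING_REACTIONS = {
    "CYP121": "aryl_cc_coupling",
    "N-oxygenase": "ring_n_oxidation",
    "AlbA": "alpha_beta_dehydrogenation",
    "Ndas_1149": "o_methylation",
    "Amir_4628": "ring_n_methylation",
    "Ndas_1145": "amide_on_methylation",
}


@dataclass
class DomainModel:
    name: str
    category: str
    hmm: ProfileHmm
    reaction_ref: str | None = None

    def __post_init__(self) -> None:
        if self.category not in DOMAIN_CATEGORIES:
            raise ValueError(f"unknown domain category {self.category!r}")
        if self.category == "cdps_tailoring" and self.reaction_ref is None:
            raise ValueError(f"{self.name}: cdps_tailoring domains need a reaction_ref")


@dataclass
class DomainHit:
    orf_id: str
    domain: str
    category: str
    bitscore: float
    reaction_ref: str | None = None


@dataclass
class GeneCluster:
    cluster_id: str
    contig_id: str
    cdps_orfs: list[OrfCall]
    window: tuple[int, int]
    member_orfs: list[OrfCall]
    domain_hits: list[DomainHit] = field(default_factory=list)
    unannotated_orfs: list[str] = field(default_factory=list)

    @property
    def domains(self) -> list[str]:
        """Primary (best-per-ORF) domain names, sorted, unique."""
        best: dict[str, DomainHit] = {}
        for h in self.domain_hits:
            if h.orf_id not in best or h.bitscore > best[h.orf_id].bitscore:
                best[h.orf_id] = h
        return sorted({h.domain for h in best.values()})


def load_domain_library(manifest_path: str | Path) -> list[DomainModel]:
    """Load a domain library: a manifest YAML next to seed alignment files.

    Manifest entries: name, category, seed (relative path), optional
    reaction, optional cutoff_margin_bits.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    models = []
    for entry in manifest["domains"]:
        seed = SeedAlignment.from_file(manifest_path.parent / entry["seed"])
        hmm = build_profile(seed, name=entry["name"])
        set_cutoff_from_seeds(
            hmm,
            [s.replace("-", "") for _, s in seed.rows],
            margin_bits=float(entry.get("cutoff_margin_bits", 10.0)),
        )
        models.append(
            DomainModel(
                name=entry["name"],
                category=entry["category"],
                hmm=hmm,
                reaction_ref=entry.get("reaction"),
            )
        )
    return models


def assemble_clusters(
    cdps_hits: list[HmmHit],
    orfs: list[OrfCall],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[GeneCluster]:
    """Group CDPS hits into gene clusters with merged +-window_bp windows.

    Windows are measured from CDPS ORF boundaries and clipped at contig
    position 0; member ORFs are those overlapping the merged window by at
    least one base. Deterministic: clusters are sorted by (contig, start)
    and ids are ``cluster_<contig>_<index>``.
    """
    orf_by_id = {o.id: o for o in orfs}
    cdps_by_contig: dict[str, list[OrfCall]] = {}
    for hit in cdps_hits:
        orf = orf_by_id.get(hit.protein_id)
        if orf is None:
            raise ValueError(f"CDPS hit {hit.protein_id!r} has no matching ORF")
        cdps_by_contig.setdefault(orf.contig_id, []).append(orf)

    clusters: list[GeneCluster] = []
    for contig in sorted(cdps_by_contig):
        anchors = sorted(cdps_by_contig[contig], key=lambda o: (o.start, o.end))
        groups: list[list[OrfCall]] = []
        cur: list[OrfCall] = []
        cur_end = -1
        for orf in anchors:
            w_start = max(0, orf.start - window_bp)
            w_end = orf.end + window_bp
            if cur and w_start <= cur_end:
                cur.append(orf)
                cur_end = max(cur_end, w_end)
            else:
                if cur:
                    groups.append(cur)
                cur = [orf]
                cur_end = w_end
        if cur:
            groups.append(cur)
        for idx, group in enumerate(groups):
            w_start = max(0, min(o.start for o in group) - window_bp)
            w_end = max(o.end for o in group) + window_bp
            members = [
                o
                for o in orfs
                if o.contig_id == contig and o.start < w_end and o.end > w_start
            ]
            members.sort(key=lambda o: (o.start, o.end))
            clusters.append(
                GeneCluster(
                    cluster_id=f"cluster_{contig}_{idx}",
                    contig_id=contig,
                    cdps_orfs=group,
                    window=(w_start, w_end),
                    member_orfs=members,
                )
            )
    return clusters


def annotate_domains(cluster: GeneCluster, library: list[DomainModel]) -> GeneCluster:
    """Score each non-CDPS member ORF against all domain models in place.

    All hits above their model cutoffs are logged; ORFs with no hit go to
    ``unannotated_orfs``. Returns the cluster for chaining.
    """
    cdps_ids = {o.id for o in cluster.cdps_orfs}
    hits: list[DomainHit] = []
    unannotated: list[str] = []
    for orf in cluster.member_orfs:
        if orf.id in cdps_ids or not orf.protein:
            continue
        orf_hits = []
        for model in library:
            score = score_protein(model.hmm, orf.protein)
            if score >= model.hmm.bitscore_cutoff:
                orf_hits.append(
                    DomainHit(
                        orf_id=orf.id,
                        domain=model.name,
                        category=model.category,
                        bitscore=score,
                        reaction_ref=model.reaction_ref,
                    )
                )
        if orf_hits:
            orf_hits.sort(key=lambda h: (-h.bitscore, h.domain))
            hits.extend(orf_hits)
        else:
            unannotated.append(orf.id)
    cluster.domain_hits = hits
    cluster.unannotated_orfs = unannotated
    return cluster


def primary_domains(cluster: GeneCluster) -> dict[str, DomainHit]:
    """Best (highest bitscore) domain hit per ORF."""
    best: dict[str, DomainHit] = {}
    for h in cluster.domain_hits:
        if h.orf_id not in best or h.bitscore > best[h.orf_id].bitscore:
            best[h.orf_id] = h
    return best


def tally_cooccurrence(clusters: list[GeneCluster]) -> dict:
    """Domain frequencies and symmetric pair counts over unique clusters.

    ``frequency[d]`` is the number of clusters containing domain d (as a
    primary annotation); ``pairs[(a, b)]`` with a < b counts clusters
    containing both.
    """
    frequency: dict[str, int] = {}
    pairs: dict[tuple[str, str], int] = {}
    for cluster in clusters:
        doms = cluster.domains
        for d in doms:
            frequency[d] = frequency.get(d, 0) + 1
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                key = (doms[i], doms[j])
                pairs[key] = pairs.get(key, 0) + 1
    return {"frequency": frequency, "pairs": pairs}


def cluster_to_dict(cluster: GeneCluster) -> dict:
    return {
        "cluster_id": cluster.cluster_id,
        "contig_id": cluster.contig_id,
        "window": list(cluster.window),
        "cdps_orfs": [o.id for o in cluster.cdps_orfs],
        "member_orfs": [o.id for o in cluster.member_orfs],
        "domain_hits": [
            {
                "orf_id": h.orf_id,
                "domain": h.domain,
                "category": h.category,
                "bitscore": h.bitscore,
                "reaction_ref": h.reaction_ref,
            }
            for h in cluster.domain_hits
        ],
        "unannotated_orfs": list(cluster.unannotated_orfs),
    }


def export_gff(clusters: list[GeneCluster], path: str | Path) -> None:
    """GFF3 export with member CDS features nested under a cluster feature."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cluster in clusters:
            prim = primary_domains(cluster)
            fh.write(
                "\t".join(
                    [
                        cluster.contig_id,
                        "cdpsmine",
                        "biosynthetic_gene_cluster",
                        str(cluster.window[0] + 1),
                        str(cluster.window[1]),
                        ".",
                        ".",
                        ".",
                        f"ID={cluster.cluster_id}",
                    ]
                )
                + "\n"
            )
            cdps_ids = {o.id for o in cluster.cdps_orfs}
            for orf in cluster.member_orfs:
                if orf.id in cdps_ids:
                    role = "CDPS"
                elif orf.id in prim:
                    role = prim[orf.id].domain
                else:
                    role = "unannotated"
                attrs = f"ID={orf.id};Parent={cluster.cluster_id};role={role}"
                fh.write(
                    "\t".join(
                        [
                            cluster.contig_id,
                            "cdpsmine",
                            "CDS",
                            str(orf.start + 1),
                            str(orf.end),
                            ".",
                            orf.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )
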