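"""Format readers/writers: SAM, FASTA, VCF, haplogroup definitions, tables.

Coordinates are 1-based inclusive throughout (SAM/VCF convention). SAM is the
required aligned-read interchange; only pure-match CIGARs are accepted (the
simulator never emits anything else, and soft-clip handling is out of scope),
other records are tallied and skipped.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .haplo import HaploDefs, Variant
from .popgen import SitePanel, is_transversion
from .qc import AlignedReadSet, Read

log = logging.getLogger("ancientkin")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(reference: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict:
    out: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        out[name] = "".join(chunks)
    return out


# ---------------------------------------------------------------------------
# SAM


def write_sam(rs: AlignedReadSet, path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in rs.reference.items()],
        "RG": [{"ID": rs.sample_id, "SM": rs.sample_id}],
    }
    tid = {c: i for i, c in enumerate(rs.reference)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(rs.reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"{rs.sample_id}.{i}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.contig]
            a.reference_start = r.start - 1
            a.mapping_quality = r.mapq
            a.cigartuples = [(0, len(r.seq))]
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals))
            a.set_tag("RG", rs.sample_id)
            fh.write(a)


def read_sam(path, reference: Mapping[str, str],
             sample_id: Optional[str] = None) -> AlignedReadSet:
    """Load a SAM file into an AlignedReadSet.

    Unmapped reads and reads whose CIGAR is not a single match run are
    counted and skipped (logged). Contigs absent from the reference raise.
    """
    reads = []
    n_unmapped = n_nonmatch = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"SAM {path} has no sequence header")
        for a in fh:
            if a.is_unmapped:
                n_unmapped += 1
                continue
            ct = a.cigartuples
            if ct is None or len(ct) != 1 or ct[0][0] != 0:
                n_nonmatch += 1
                continue
            contig = a.reference_name
            if contig not in reference:
                raise ValueError(
                    f"record {a.query_name!r} maps to unknown contig {contig!r}")
            quals = tuple(int(q) for q in a.query_qualities)
            reads.append(Read(contig, a.reference_start + 1,
                              "-" if a.is_reverse else "+",
                              a.query_sequence.upper(), quals,
                              int(a.mapping_quality)))
    if n_unmapped or n_nonmatch:
        log.info("read_sam(%s): skipped %d unmapped, %d non-pure-match records",
                 path, n_unmapped, n_nonmatch)
    if sample_id is None:
        sample_id = Path(path).stem
    return AlignedReadSet(reads, reference, sample_id)


# ---------------------------------------------------------------------------
# VCF + labels


def write_panel_vcf(panel: SitePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ancientkin-simulate\n")
        contigs = dict.fromkeys(panel.sites["contig"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.individuals) + "\n")
        G = panel.genotypes
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j in range(panel.n_sites):
            row = panel.sites.iloc[j]
            gts = "\t".join(gt_map[int(G[i, j])] for i in range(len(panel.individuals)))
            fh.write(f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_labels(panel: SitePanel, path) -> None:
    pd.DataFrame({"individual": panel.individuals,
                  "population": [panel.labels[i] for i in panel.individuals]}
                 ).to_csv(path, sep="\t", index=False)


def read_panel_vcf(path, labels_path, transversions_only: bool = True) -> SitePanel:
    """Load a biallelic SNP panel with GT fields plus a population-label TSV.

    Multi-allelic, indel and (when ``transversions_only``) transition sites
    are dropped with a logged tally. Every VCF individual must appear in the
    label table.
    """
    labels_df = pd.read_csv(labels_path, sep="\t")
    label_map = dict(zip(labels_df["individual"], labels_df["population"]))
    rows, genos = [], []
    n_drop_multi = n_drop_ts = 0
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        missing = [s for s in individuals if s not in label_map]
        if missing:
            raise ValueError(f"label file missing individuals: {missing}")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_drop_multi += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_drop_multi += 1
                continue
            tv = is_transversion(ref, alt)
            if transversions_only and not tv:
                n_drop_ts += 1
                continue
            g = []
            for s in individuals:
                gt = rec.samples[s]["GT"]
                if gt is None or any(x is None for x in gt):
                    g.append(-1)
                else:
                    g.append(int(sum(gt)))
            rows.append((rec.chrom, rec.pos, ref, alt, tv))
            genos.append(g)
    if n_drop_multi or n_drop_ts:
        log.info("read_panel_vcf(%s): dropped %d non-biallelic-SNP, "
                 "%d transition sites", path, n_drop_multi, n_drop_ts)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt",
                                        "is_transversion"])
    G = (np.asarray(genos, dtype=np.int8).T if genos
         else np.zeros((len(individuals), 0), dtype=np.int8))
    return SitePanel(sites, G, individuals, {s: label_map[s] for s in individuals})


# ---------------------------------------------------------------------------
# haplogroup definitions (Newick + variants TSV)


def write_haplo_defs(defs: HaploDefs, newick_path, variants_path) -> None:
    def render(node: str) -> str:
        ch = defs.children[node]
        if not ch:
            return node
        return "(" + ",".join(render(c) for c in sorted(ch)) + ")" + node

    with open(newick_path, "w") as fh:
        fh.write(render(defs.root) + ";\n")
    rows = []
    for node in defs.nodes():
        for v in defs.variants.get(node, []):
            rows.append((node, defs.contig, v.pos, v.anc, v.der))
    pd.DataFrame(rows, columns=["haplogroup", "contig", "pos", "anc", "der"]
                 ).to_csv(variants_path, sep="\t", index=False)


def read_haplo_defs(newick_path, variants_path) -> HaploDefs:
    import dendropy
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                             suppress_internal_node_taxa=False)
    parent: dict = {}

    def name_of(node):
        return node.taxon.label if node.taxon else node.label

    for node in tree.preorder_node_iter():
        nm = name_of(node)
        if nm is None:
            raise ValueError("haplogroup tree has an unlabelled node")
        nm = nm.replace(" ", "_")
        parent[nm] = (name_of(node.parent_node).replace(" ", "_")
                      if node.parent_node else None)
    vdf = pd.read_csv(variants_path, sep="\t")
    variants: dict = {n: [] for n in parent}
    contig = vdf["contig"].iloc[0] if len(vdf) else "chrMT"
    for _, row in vdf.iterrows():
        variants[row["haplogroup"]].append(
            Variant(int(row["pos"]), row["anc"], row["der"]))
    return HaploDefs(parent, variants, contig=contig)


# ---------------------------------------------------------------------------
# tables and provenance


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (for output provenance)."""
    import yaml
    canon = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: Optional[Mapping] = None) -> None:
    """TSV with '#key=value' provenance header lines (config hash, seed)."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
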