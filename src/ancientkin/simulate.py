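"""Synthetic-data generator for the whole pipeline, with known ground truth.

Emulates the statistical structure of shotgun data from poorly preserved
Neolithic skeletons: short fragments (lognormal lengths, means around
39-45.5 bp), 5' C→T deamination with geometric positional decay (rates up
to ~30% at position 1, mirrored 3' G→A as in double-stranded blunt-end
libraries), low endogenous content (0.1-14.7%), percent-level present-day
human contamination, sex-dependent X/Y read allocation, and a Balding-
Nichols SNP panel of K source populations plus admixed individuals with
known ancestry fractions. Every quantity the pipeline later estimates is
recorded in a TruthRecord.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chrono import CalCurve
from .haplo import HaploDefs, Variant
from .popgen import SitePanel, is_transversion
from .qc import AlignedReadSet, Read, revcomp

BASES = np.array(list("ACGT"))
# transversion partners of each base
_TV_PARTNERS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}

AUTOSOME, CHRX, CHRY, CHRMT = "auto1", "chrX", "chrY", "chrMT"


def _stream(seed: int, *keys) -> np.random.Generator:
    """Independent RNG stream derived from a root seed and stable name hashes."""
    ints = [seed] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(ints)


@dataclass
class ReadSpec:
    """Sequencing/damage configuration for one simulated sample."""

    sample_id: str
    sex: str = "XY"
    endogenous_fraction: float = 0.05
    mean_fragment_bp: float = 45.0
    coverage_x: float = 0.5
    deamination_rate_5p: float = 0.25
    deamination_decay: float = 0.5
    seq_error_rate: float = 0.001
    contamination_fraction: float = 0.01
    ancestry: Optional[tuple] = None   # Q over source pops; None -> pop 0
    mt_haplogroup: Optional[str] = None
    y_haplogroup: Optional[str] = None
    duplicate_rate: float = 0.0

    def __post_init__(self):
        if self.sex not in ("XX", "XY"):
            raise ValueError(f"sex must be 'XX' or 'XY', got {self.sex!r}")
        for name in ("endogenous_fraction", "deamination_rate_5p",
                     "contamination_fraction", "seq_error_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.deamination_decay < 1.0:
            raise ValueError(f"deamination_decay must lie in (0, 1), got {self.deamination_decay}")
        if self.coverage_x <= 0:
            raise ValueError(f"coverage_x must be positive, got {self.coverage_x}")
        if self.mean_fragment_bp < 30:
            raise ValueError("mean_fragment_bp must be >= 30 (read minimum length)")
        if self.ancestry is not None:
            q = np.asarray(self.ancestry, dtype=float)
            if q.min() < 0 or abs(q.sum() - 1.0) > 1e-8:
                raise ValueError("ancestry must be a probability vector summing to 1")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length_bp: int = 100_000
    x_length_bp: int = 20_000
    y_length_bp: int = 2_000
    mt_length_bp: int = 16_000
    n_source_pops: int = 3
    fst_per_pop: Sequence[float] = (0.1, 0.1, 0.1)
    n_panel_per_pop: int = 10
    n_snps: int = 2_000
    n_x_snps: int = 200
    admixed_specs: Sequence[tuple] = ()   # (q vector, label)
    read_specs: Sequence[ReadSpec] = ()
    mt_copy_factor: float = 50.0
    frag_sigma_log: float = 0.35
    low_mapq_frac: float = 0.03
    low_bq_frac: float = 0.02
    contaminant_divergence: float = 0.01  # substitutions per bp on mtDNA

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_source_pops < 1:
            raise ValueError("n_source_pops must be >= 1")
        if len(self.fst_per_pop) != self.n_source_pops:
            raise ValueError("fst_per_pop must list one drift parameter per source population")
        for f in self.fst_per_pop:
            if not 0.0 < f < 1.0:
                raise ValueError(f"fst_per_pop entries must lie in (0, 1), got {f}")
        for q, label in self.admixed_specs:
            qa = np.asarray(q, dtype=float)
            if len(qa) != self.n_source_pops:
                raise ValueError(f"admixed_specs[{label!r}] Q length != n_source_pops")
            if qa.min() < 0 or abs(qa.sum() - 1.0) > 1e-8:
                raise ValueError(f"admixed_specs[{label!r}] Q must sum to 1")
        ids = [rs.sample_id for rs in self.read_specs]
        if len(ids) != len(set(ids)):
            raise ValueError("read_specs sample_ids must be unique")

    @property
    def compartment_lengths(self) -> dict:
        return {AUTOSOME: self.genome_length_bp, CHRX: self.x_length_bp,
                CHRY: self.y_length_bp, CHRMT: self.mt_length_bp}


@dataclass
class SampleTruth:
    sample_id: str
    sex: str
    contamination_fraction: float
    deamination_rate_5p: float
    deamination_decay: float
    mt_haplogroup: str
    y_haplogroup: Optional[str]
    q: np.ndarray
    n_raw_total: int = 0
    n_duplicates_injected: int = 0
    genotypes: Optional[np.ndarray] = None     # diploid dosage at panel sites
    x_alleles: Optional[np.ndarray] = None     # haploid alleles at X sites (XY only)


@dataclass
class TruthRecord:
    """Ground truth for every simulated object, keyed for recovery tests."""

    panel_f: Optional[np.ndarray] = None          # K x n_snps frequencies
    panel_q: dict = field(default_factory=dict)   # individual -> Q vector
    ancestral_freq: Optional[np.ndarray] = None
    samples: dict = field(default_factory=dict)   # sample_id -> SampleTruth
    mt_defs: Optional[HaploDefs] = None
    y_defs: Optional[HaploDefs] = None
    contaminant_mt: dict = field(default_factory=dict)   # pos -> base
    contaminant_x_genotypes: Optional[np.ndarray] = None
    contaminant_genotypes: Optional[np.ndarray] = None


def build_reference(cfg: SimulationConfig) -> dict:
    """Deterministic synthetic reference: one contig per compartment."""
    ref = {}
    for contig, length in cfg.compartment_lengths.items():
        rng = _stream(cfg.seed, "reference", contig)
        ref[contig] = "".join(BASES[rng.integers(0, 4, size=length)])
    return ref


# ---------------------------------------------------------------------------
# SNP panel


def simulate_panel(cfg: SimulationConfig) -> tuple[SitePanel, TruthRecord]:
    """Balding-Nichols panel of K populations plus admixed individuals.

    Per site an ancestral frequency p ~ U(0.05, 0.95); population k drifts to
    f_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), giving Var(f_k) =
    F_k p(1-p). Sites are restricted to transversion ref/alt pairs (ref is
    the genome base) and diploid genotypes are binomial draws; admixed
    individuals draw from mixture frequencies Q·F.
    """
    rng = _stream(cfg.seed, "panel")
    ref = build_reference(cfg)
    positions = np.sort(rng.choice(np.arange(1, cfg.genome_length_bp + 1),
                                   size=cfg.n_snps, replace=False))
    refs = np.array([ref[AUTOSOME][p - 1] for p in positions])
    alts = np.array([_TV_PARTNERS[b][rng.integers(2)] for b in refs])
    sites = pd.DataFrame({
        "contig": AUTOSOME, "pos": positions, "ref": refs, "alt": alts,
        "is_transversion": [is_transversion(r, a) for r, a in zip(refs, alts)],
    })
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    K = cfg.n_source_pops
    F = np.empty((K, cfg.n_snps))
    for k, fst in enumerate(cfg.fst_per_pop):
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        F[k] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
    individuals, genos, labels, q_truth = [], [], {}, {}
    for k in range(K):
        for i in range(cfg.n_panel_per_pop):
            name = f"pop{k}_{i}"
            individuals.append(name)
            genos.append(rng.binomial(2, F[k]))
            labels[name] = f"pop{k}"
            q = np.zeros(K)
            q[k] = 1.0
            q_truth[name] = q
    for q, label in cfg.admixed_specs:
        q = np.asarray(q, dtype=float)
        individuals.append(label)
        genos.append(rng.binomial(2, q @ F))
        labels[label] = "admixed"
        q_truth[label] = q
    x_sites = None
    if cfg.n_x_snps > 0:
        xrng = _stream(cfg.seed, "panel", "x")
        xpos = np.sort(xrng.choice(np.arange(1, cfg.x_length_bp + 1),
                                   size=cfg.n_x_snps, replace=False))
        xrefs = np.array([ref[CHRX][p - 1] for p in xpos])
        xalts = np.array([_TV_PARTNERS[b][xrng.integers(2)] for b in xrefs])
        x_sites = pd.DataFrame({"contig": CHRX, "pos": xpos, "ref": xrefs,
                                "alt": xalts,
                                "f": xrng.uniform(0.1, 0.9, size=cfg.n_x_snps)})
    panel = SitePanel(sites, np.asarray(genos, dtype=np.int8), individuals,
                      labels, x_sites=x_sites)
    truth = TruthRecord(panel_f=F, panel_q=q_truth, ancestral_freq=p_anc)
    return panel, truth


# ---------------------------------------------------------------------------
# haplogroup definitions


def simulate_haplo_defs(cfg: SimulationConfig, contig: str = CHRMT,
                        depth: int = 2, n_children: int = 2,
                        variants_per_branch: int = 4) -> HaploDefs:
    """Balanced synthetic haplogroup tree with transversion defining variants.

    Node names encode the path (root "HG", children "HG_A", "HG_B",
    grandchildren "HG_AA" ...); every branch carries
    ``variants_per_branch`` variants at unique positions whose ancestral
    state is the reference base and derived state a transversion partner, so
    deamination cannot mimic them.
    """
    ref = build_reference(cfg)[contig]
    rng = _stream(cfg.seed, "haplodefs", contig)
    n_branches = sum(n_children ** d for d in range(1, depth + 1))
    pool = rng.choice(np.arange(1, len(ref) + 1),
                      size=n_branches * variants_per_branch, replace=False)
    parent = {"HG": None}
    variants = {"HG": []}
    frontier = ["HG"]
    cursor = 0
    letters = string.ascii_uppercase
    for _ in range(depth):
        nxt = []
        for node in frontier:
            suffix = node.split("HG_")[-1] if node != "HG" else ""
            for c in range(n_children):
                child = f"HG_{suffix}{letters[c]}"
                parent[child] = node
                vs = []
                for _ in range(variants_per_branch):
                    pos = int(pool[cursor])
                    cursor += 1
                    anc = ref[pos - 1]
                    der = _TV_PARTNERS[anc][rng.integers(2)]
                    vs.append(Variant(pos, anc, der))
                variants[child] = sorted(vs, key=lambda v: v.pos)
                nxt.append(child)
        frontier = nxt
    return HaploDefs(parent, variants, contig=contig)


def haplotype_sequence(reference: str, defs: HaploDefs, node: str) -> str:
    """Reference with the derived alleles of root→``node`` applied."""
    seq = list(reference)
    for v in defs.path_variants(node):
        seq[v.pos - 1] = v.der
    return "".join(seq)


# ---------------------------------------------------------------------------
# reads


def _leaves(defs: HaploDefs) -> list:
    return sorted(n for n, ch in defs.children.items() if not ch)


def contaminant_mt_variants(cfg: SimulationConfig) -> dict:
    """Fixed divergent present-day mtDNA haplotype: pos -> base.

    Divergence defaults to one substitution per 100 bp, evenly spaced, using
    transversion partners so damage masking never hides it.
    """
    ref = build_reference(cfg)[CHRMT]
    rng = _stream(cfg.seed, "contaminant", "mt")
    step = max(1, int(round(1.0 / cfg.contaminant_divergence / 1.0)))
    out = {}
    for pos in range(step // 2, cfg.mt_length_bp, step):
        p1 = pos + 1
        anc = ref[pos]
        out[p1] = _TV_PARTNERS[anc][rng.integers(2)]
    return out


def _apply_damage(frag: np.ndarray, rng, delta: float, decay: float) -> np.ndarray:
    """5' C→T and mirrored 3' G→A with geometric positional decay."""
    if delta <= 0:
        return frag
    n = len(frag)
    probs = delta * decay ** np.arange(n)
    u5 = rng.random(n) < probs
    hit5 = u5 & (frag == "C")
    frag[hit5] = "T"
    u3 = rng.random(n) < probs[::-1]
    hit3 = u3 & (frag == "G") & ~hit5
    frag[hit3] = "A"
    return frag


def _apply_errors(frag: np.ndarray, rng, rate: float) -> np.ndarray:
    if rate <= 0:
        return frag
    hits = np.flatnonzero(rng.random(len(frag)) < rate)
    for i in hits:
        options = [b for b in "ACGT" if b != frag[i]]
        frag[i] = options[rng.integers(3)]
    return frag


def sex_read_allocation(sex: str, x_len: int, y_len: int) -> float:
    """Expected fraction of sex-chromosome reads mapping to Y."""
    if sex == "XX":
        return 0.0
    return y_len / (x_len + y_len)


def simulate_sex_counts(rng: np.random.Generator, sex: str, n_reads: int,
                        x_len: int, y_len: int) -> tuple[int, int]:
    """Draw (nX, nY) sex-chromosome read counts for a sample of known sex."""
    ry = sex_read_allocation(sex, x_len, y_len)
    n_y = int(rng.binomial(n_reads, ry))
    return n_reads - n_y, n_y


def simulate_reads(cfg: SimulationConfig, panel: SitePanel,
                   truth: Optional[TruthRecord] = None
                   ) -> tuple[dict, TruthRecord]:
    """Simulate aligned single-end reads for every ReadSpec in ``cfg``.

    Reads are placed uniformly per compartment at the ploidy-scaled target
    coverage (mtDNA boosted by ``mt_copy_factor``), carry lognormal fragment
    lengths, strand-symmetric placement, terminal deamination on endogenous
    reads only, uniform sequencing errors, and optional exact PCR duplicates.
    Contaminant reads come from an undamaged present-day individual (XX; a
    fixed divergent mtDNA haplotype, panel-frequency-drawn nuclear alleles).
    Returns ({sample_id: AlignedReadSet}, truth).
    """
    if truth is None:
        truth = TruthRecord()
    ref = build_reference(cfg)
    truth.mt_defs = simulate_haplo_defs(cfg, CHRMT)
    truth.y_defs = simulate_haplo_defs(cfg, CHRY)
    truth.contaminant_mt = contaminant_mt_variants(cfg)
    crng = _stream(cfg.seed, "contaminant", "nuclear")
    if truth.panel_f is not None:
        truth.contaminant_genotypes = crng.binomial(2, truth.panel_f[0]).astype(np.int8)
    else:
        truth.contaminant_genotypes = crng.binomial(
            2, np.full(panel.n_sites, 0.5)).astype(np.int8)
    if panel.x_sites is not None:
        truth.contaminant_x_genotypes = crng.binomial(
            2, panel.x_sites["f"].to_numpy()).astype(np.int8)

    site_pos = panel.sites["pos"].to_numpy()
    site_ref = panel.sites["ref"].to_numpy()
    site_alt = panel.sites["alt"].to_numpy()
    auto_map = {int(p): j for j, p in enumerate(site_pos)}
    if panel.x_sites is not None:
        x_pos = panel.x_sites["pos"].to_numpy()
        x_ref = panel.x_sites["ref"].to_numpy()
        x_alt = panel.x_sites["alt"].to_numpy()
        x_f = panel.x_sites["f"].to_numpy()
        x_map = {int(p): j for j, p in enumerate(x_pos)}
    else:
        x_map = {}

    readsets = {}
    K = cfg.n_source_pops
    for spec in cfg.read_specs:
        rng = _stream(cfg.seed, "reads", spec.sample_id)
        q = np.asarray(spec.ancestry, dtype=float) if spec.ancestry is not None \
            else np.eye(K)[0]
        if truth.panel_f is not None:
            p_site = q @ truth.panel_f
        else:
            p_site = np.full(panel.n_sites, 0.5)
        genotypes = rng.binomial(2, p_site).astype(np.int8)
        if spec.sex == "XY":
            x_all = (rng.random(len(x_map)) < x_f).astype(np.int8) if x_map else None
            x_dip = None
        else:
            x_all = None
            x_dip = rng.binomial(2, x_f).astype(np.int8) if x_map else None
        mt_hg = spec.mt_haplogroup or _leaves(truth.mt_defs)[
            rng.integers(len(_leaves(truth.mt_defs)))]
        mt_var = {v.pos: v.der for v in truth.mt_defs.path_variants(mt_hg)}
        if spec.sex == "XY":
            y_hg = spec.y_haplogroup or _leaves(truth.y_defs)[
                rng.integers(len(_leaves(truth.y_defs)))]
            y_var = {v.pos: v.der for v in truth.y_defs.path_variants(y_hg)}
        else:
            y_hg, y_var = None, {}

        ploidy = {AUTOSOME: 2.0, CHRX: 2.0 if spec.sex == "XX" else 1.0,
                  CHRY: 0.0 if spec.sex == "XX" else 1.0,
                  CHRMT: cfg.mt_copy_factor}
        reads = []
        n_pass_expected = 0
        mu_log = np.log(spec.mean_fragment_bp) - 0.5 * cfg.frag_sigma_log ** 2
        for contig, length in cfg.compartment_lengths.items():
            cov = spec.coverage_x * ploidy[contig] / 2.0
            n = int(round(cov * length / spec.mean_fragment_bp))
            if n <= 0:
                continue
            lens = np.round(rng.lognormal(mu_log, cfg.frag_sigma_log, n)
                            ).astype(int).clip(20, length)
            starts = rng.integers(1, length - lens + 2)
            minus = rng.random(n) < 0.5
            contam = rng.random(n) < spec.contamination_fraction
            mapqs = np.where(rng.random(n) < cfg.low_mapq_frac, 20, 60)
            refseq = ref[contig]
            for i in range(n):
                if contam[i] and contig == CHRY:
                    continue   # contaminant (XX) contributes no Y reads
                L = int(lens[i])
                s = int(starts[i])
                seg = np.array(list(refseq[s - 1: s - 1 + L]))
                # apply individual (or contaminant) variants
                if contig == AUTOSOME:
                    gsrc = (truth.contaminant_genotypes if contam[i] else genotypes)
                    for off in range(L):
                        j = auto_map.get(s + off)
                        if j is not None:
                            g = gsrc[j]
                            if g == 2 or (g == 1 and rng.random() < 0.5):
                                seg[off] = site_alt[j]
                elif contig == CHRX and x_map:
                    for off in range(L):
                        j = x_map.get(s + off)
                        if j is None:
                            continue
                        if contam[i]:
                            g = truth.contaminant_x_genotypes[j]
                            use_alt = g == 2 or (g == 1 and rng.random() < 0.5)
                        elif spec.sex == "XY":
                            use_alt = bool(x_all[j])
                        else:
                            g = x_dip[j]
                            use_alt = g == 2 or (g == 1 and rng.random() < 0.5)
                        if use_alt:
                            seg[off] = x_alt[j]
                elif contig == CHRMT:
                    src = truth.contaminant_mt if contam[i] else mt_var
                    for off in range(L):
                        der = src.get(s + off)
                        if der is not None:
                            seg[off] = der
                elif contig == CHRY:
                    for off in range(L):
                        der = y_var.get(s + off)
                        if der is not None:
                            seg[off] = der
                # orient to fragment 5'->3'
                if minus[i]:
                    frag = np.array(list(revcomp("".join(seg))))
                else:
                    frag = seg
                if not contam[i]:
                    frag = _apply_damage(frag, rng, spec.deamination_rate_5p,
                                         spec.deamination_decay)
                frag = _apply_errors(frag, rng, spec.seq_error_rate)
                quals = np.where(rng.random(L) < cfg.low_bq_frac, 15, 40)
                if minus[i]:
                    seq = revcomp("".join(frag))
                    quals = quals[::-1]
                else:
                    seq = "".join(frag)
                reads.append(Read(contig, s, "-" if minus[i] else "+", seq,
                                  tuple(int(x) for x in quals), int(mapqs[i])))
                if L >= 30 and mapqs[i] >= 30:
                    n_pass_expected += 1
        # exact duplicates
        n_dup = 0
        if spec.duplicate_rate > 0 and reads:
            n_dup = int(rng.binomial(len(reads), spec.duplicate_rate))
            for idx in rng.integers(0, len(reads), size=n_dup):
                reads.append(reads[int(idx)])
        rs = AlignedReadSet(reads, ref, spec.sample_id).sorted()
        readsets[spec.sample_id] = rs
        n_raw = (int(round(n_pass_expected / spec.endogenous_fraction))
                 if spec.endogenous_fraction > 0 else n_pass_expected)
        truth.samples[spec.sample_id] = SampleTruth(
            sample_id=spec.sample_id, sex=spec.sex,
            contamination_fraction=spec.contamination_fraction,
            deamination_rate_5p=spec.deamination_rate_5p,
            deamination_decay=spec.deamination_decay,
            mt_haplogroup=mt_hg, y_haplogroup=y_hg, q=q,
            n_raw_total=max(n_raw, 1), n_duplicates_injected=n_dup,
            genotypes=genotypes, x_alleles=x_all)
    return readsets, truth


def simulate_mt_reads(seed: int, reference_mt: str,
                      endo_variants: Mapping[int, str],
                      contam_variants: Mapping[int, str],
                      n_reads: int, contamination: float,
                      mean_fragment_bp: float = 45.0,
                      deamination_rate_5p: float = 0.25,
                      deamination_decay: float = 0.5,
                      seq_error_rate: float = 0.001,
                      frag_sigma_log: float = 0.35,
                      contig: str = CHRMT) -> AlignedReadSet:
    """Fast mtDNA-only read simulator for contamination calibration studies.

    Endogenous reads carry ``endo_variants`` and terminal damage; a
    ``contamination`` fraction of reads instead carry ``contam_variants``
    and no damage. Same read model as :func:`simulate_reads`.
    """
    rng = np.random.default_rng(seed)
    length = len(reference_mt)
    mu_log = np.log(mean_fragment_bp) - 0.5 * frag_sigma_log ** 2
    lens = np.round(rng.lognormal(mu_log, frag_sigma_log, n_reads)
                    ).astype(int).clip(20, length)
    starts = rng.integers(1, length - lens + 2)
    minus = rng.random(n_reads) < 0.5
    contam = rng.random(n_reads) < contamination
    reads = []
    for i in range(n_reads):
        L, s = int(lens[i]), int(starts[i])
        seg = np.array(list(reference_mt[s - 1: s - 1 + L]))
        src = contam_variants if contam[i] else endo_variants
        for off in range(L):
            der = src.get(s + off)
            if der is not None:
                seg[off] = der
        frag = np.array(list(revcomp("".join(seg)))) if minus[i] else seg
        if not contam[i]:
            frag = _apply_damage(frag, rng, deamination_rate_5p, deamination_decay)
        frag = _apply_errors(frag, rng, seq_error_rate)
        seq = revcomp("".join(frag)) if minus[i] else "".join(frag)
        reads.append(Read(contig, s, "-" if minus[i] else "+", seq,
                          tuple([40] * L), 60))
    return AlignedReadSet(reads, {contig: reference_mt}, "mtsim").sorted()


# ---------------------------------------------------------------------------
# calibration curve


def simulate_calcurve(seed: int, span_calbp: float, wiggle_sd: float,
                      grid_step: float = 1.0, sigma_curve: float = 10.0,
                      wiggle_scale: float = 150.0) -> CalCurve:
    """Synthetic calibration curve: identity mapping plus smooth wiggle.

    mu(theta) = theta + w(theta) where w is Gaussian-smoothed noise with
    standard deviation ``wiggle_sd`` and correlation length ``wiggle_scale``
    years; wiggle_sd=0 gives the exact identity curve. The curve sigma is
    constant ``sigma_curve``.
    """
    if span_calbp <= 0:
        raise ValueError("span must be positive")
    if wiggle_sd < 0:
        raise ValueError("wiggle_sd must be non-negative")
    if sigma_curve <= 0:
        raise ValueError("curve sigma must be positive")
    grid = np.arange(0.0, span_calbp + 0.5 * grid_step, grid_step)
    if wiggle_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, 1.0, size=len(grid))
        from scipy.ndimage import gaussian_filter1d
        smooth = gaussian_filter1d(noise, sigma=wiggle_scale / grid_step,
                                   mode="reflect")
        sd = smooth.std()
        wiggle = smooth / sd * wiggle_sd if sd > 0 else np.zeros_like(smooth)
    else:
        wiggle = np.zeros_like(grid)
    mu = grid + wiggle
    return CalCurve(grid, mu, np.full(len(grid), float(sigma_curve)),
                    name=f"synthetic(seed={seed})")
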