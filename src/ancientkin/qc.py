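"""Read-level QC and ancient-DNA damage authentication.

Implements the screening statistics used to authenticate shotgun data from
degraded skeletal samples: mapping-quality/length filtering, duplicate
collapse, terminal C→T / G→A deamination profiles, endogenous content and
depth of coverage, and the pass/fail screening decision used to select
samples for deeper sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A single-end aligned read with pure-match alignment.

    ``start`` is 1-based on ``contig``; ``strand`` is '+' or '-'; ``seq`` is
    stored reference-oriented (SAM convention), so a '-' read must be
    reverse-complemented to recover the sequenced fragment orientation.
    """

    contig: str
    start: int
    strand: str
    seq: str
    quals: tuple
    mapq: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"read start must be >= 1, got {self.start}")
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end(self) -> int:
        """1-based inclusive end of the alignment."""
        return self.start + len(self.seq) - 1


@dataclass
class AlignedReadSet:
    """Coordinate-sorted single-end reads plus a reference accessor.

    ``reference`` maps contig name to its full sequence (upper-case).
    """

    reads: list
    reference: Mapping[str, str]
    sample_id: str = "sample"

    def __len__(self):
        return len(self.reads)

    def is_sorted(self) -> bool:
        prev = {}
        order = []
        for r in self.reads:
            if r.contig not in prev:
                order.append(r.contig)
            elif r.contig != order[-1]:
                return False  # contig revisited: not grouped
            if r.contig in prev and r.start < prev[r.contig]:
                return False
            prev[r.contig] = r.start
        return True

    def sorted(self) -> "AlignedReadSet":
        contigs = list(self.reference)
        rank = {c: i for i, c in enumerate(contigs)}
        reads = sorted(self.reads, key=lambda r: (rank.get(r.contig, len(rank)), r.start, r.strand, r.seq))
        return AlignedReadSet(reads, self.reference, self.sample_id)

    def on_contig(self, contig: str) -> "AlignedReadSet":
        return AlignedReadSet([r for r in self.reads if r.contig == contig],
                              self.reference, self.sample_id)


@dataclass
class DamageProfile:
    """Per-position terminal misincorporation frequencies.

    ``ct5[p]`` is the C→T frequency at offset ``p`` from the 5' end of the
    sequenced fragment, ``ga3[p]`` the G→A frequency at offset ``p`` from the
    3' end. Positions with zero opportunities are NaN (missing), never 0.
    """

    window: int
    ct5: np.ndarray
    ga3: np.ndarray
    ct5_opportunities: np.ndarray
    ga3_opportunities: np.ndarray


@dataclass
class SampleQC:
    """Screening summary for one sample (one row of a QC table)."""

    sample_id: str
    endogenous_pct: float
    doc_nuclear: float
    doc_mt: float
    mean_fragment_bp: float
    n_reads_raw: int
    n_reads_postfilter: int
    n_duplicates_removed: int = 0


def filter_reads(rs: AlignedReadSet, min_mapq: int = 30, min_len: int = 30) -> AlignedReadSet:
    """Keep reads with mapping quality >= ``min_mapq`` and length >= ``min_len``.

    Both boundaries are inclusive; input order is preserved.
    """
    kept = [r for r in rs.reads if r.mapq >= min_mapq and len(r.seq) >= min_len]
    return AlignedReadSet(kept, rs.reference, rs.sample_id)


def _dup_key(r: Read):
    # 5' alignment position of the fragment: leftmost coordinate for '+',
    # rightmost for '-'.
    pos5 = r.start if r.strand == "+" else r.end
    return (r.contig, pos5, r.strand, len(r.seq))


def collapse_duplicates(rs: AlignedReadSet) -> tuple[AlignedReadSet, int]:
    """Collapse PCR/optical duplicates sharing (contig, 5' position, strand, length).

    Among duplicates the read with the highest summed base quality is kept;
    ties break deterministically on lexicographically smallest sequence.
    Requires coordinate-sorted input.
    """
    if not rs.is_sorted():
        raise ValueError("collapse_duplicates requires coordinate-sorted input")
    best: dict = {}
    order: list = []
    for r in rs.reads:
        key = _dup_key(r)
        cur = best.get(key)
        if cur is None:
            best[key] = r
            order.append(key)
        else:
            # higher summed quality wins; tie -> smaller sequence
            if (sum(r.quals), [-ord(c) for c in r.seq]) > (sum(cur.quals), [-ord(c) for c in cur.seq]):
                best[key] = r
    kept = AlignedReadSet([best[k] for k in order], rs.reference, rs.sample_id).sorted()
    return kept, len(rs.reads) - len(kept.reads)


def _oriented(read: Read, reference: Mapping[str, str]) -> tuple[str, str]:
    """Return (read sequence, reference sequence) in fragment 5'→3' orientation."""
    ref = reference[read.contig][read.start - 1: read.end]
    if read.strand == "-":
        return revcomp(read.seq), revcomp(ref)
    return read.seq, ref


def damage_profile(rs: AlignedReadSet, window: int = 25) -> DamageProfile:
    """Terminal deamination profile: C→T from the 5' end, G→A from the 3' end.

    Reverse-strand reads are re-oriented to sequencing (fragment) direction
    before counting, so the profile reflects damage chemistry, not reference
    strand. Frequencies at positions with no opportunities are NaN.
    """
    ct_hits = np.zeros(window, dtype=np.int64)
    ct_opp = np.zeros(window, dtype=np.int64)
    ga_hits = np.zeros(window, dtype=np.int64)
    ga_opp = np.zeros(window, dtype=np.int64)
    for r in rs.reads:
        seq, ref = _oriented(r, rs.reference)
        n = len(seq)
        w5 = min(window, n)
        for p in range(w5):
            if ref[p] == "C":
                ct_opp[p] += 1
                if seq[p] == "T":
                    ct_hits[p] += 1
        for p in range(w5):
            if ref[n - 1 - p] == "G":
                ga_opp[p] += 1
                if seq[n - 1 - p] == "A":
                    ga_hits[p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(ct_opp > 0, ct_hits / np.maximum(ct_opp, 1), np.nan)
        ga3 = np.where(ga_opp > 0, ga_hits / np.maximum(ga_opp, 1), np.nan)
    return DamageProfile(window, ct5, ga3, ct_opp, ga_opp)


def sample_qc(rs_raw_total: int, rs: AlignedReadSet,
              compartment_lengths: Mapping[str, int],
              mt_contig: str = "chrMT",
              n_duplicates_removed: int = 0) -> SampleQC:
    """Endogenous content and depth of coverage from post-filter reads.

    ``endogenous_pct`` = 100 x mapped post-filter reads / total raw reads.
    DoC per compartment = total aligned bases / compartment length; the
    nuclear DoC pools every non-mitochondrial compartment.
    """
    if rs_raw_total <= 0:
        raise ValueError("sample_qc requires a positive raw read total")
    for c, ln in compartment_lengths.items():
        if ln <= 0:
            raise ValueError(f"compartment {c!r} has non-positive length")
    n = len(rs.reads)
    bases = {c: 0 for c in compartment_lengths}
    total_len = 0
    for r in rs.reads:
        total_len += len(r.seq)
        if r.contig in bases:
            bases[r.contig] += len(r.seq)
    nuc_len = sum(ln for c, ln in compartment_lengths.items() if c != mt_contig)
    nuc_bases = sum(b for c, b in bases.items() if c != mt_contig)
    doc_nuc = nuc_bases / nuc_len if nuc_len else 0.0
    doc_mt = (bases.get(mt_contig, 0) / compartment_lengths[mt_contig]
              if mt_contig in compartment_lengths else 0.0)
    return SampleQC(
        sample_id=rs.sample_id,
        endogenous_pct=100.0 * n / rs_raw_total,
        doc_nuclear=doc_nuc,
        doc_mt=doc_mt,
        mean_fragment_bp=(total_len / n) if n else float("nan"),
        n_reads_raw=rs_raw_total,
        n_reads_postfilter=n,
        n_duplicates_removed=n_duplicates_removed,
    )


def screen_sample(qc: SampleQC, dp: DamageProfile,
                  min_endo_pct: float = 0.5,
                  min_ct5_pct: float = 10.0) -> tuple[str, list]:
    """Screening decision for deeper sequencing.

    A sample passes when endogenous content >= ``min_endo_pct`` percent AND
    first-position 5' C→T damage >= ``min_ct5_pct`` percent (both inclusive,
    the complement of the exclusion rule "<0.5% endogenous and <10% damage").
    Returns ("pass"|"fail", reasons).
    """
    reasons = []
    if dp.ct5_opportunities[0] == 0 or np.isnan(dp.ct5[0]):
        return "fail", ["insufficient damage opportunities"]
    if qc.endogenous_pct < min_endo_pct:
        reasons.append(f"endogenous content {qc.endogenous_pct:.2f}% < {min_endo_pct}%")
    if 100.0 * dp.ct5[0] < min_ct5_pct:
        reasons.append(f"5' C-T damage {100 * dp.ct5[0]:.1f}% < {min_ct5_pct}%")
    return ("pass" if not reasons else "fail"), reasons
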