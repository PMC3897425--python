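"""Observation-window construction and per-window read counting.

Read-depth CNV calling compares observed read counts (RC) against an
expectation per genomic window.  Because mappability varies along the
genome, fixed-width windows have unequal expected RC; instead the genome
is tiled with variable-width windows that each contain the same number of
uniquely-mappable simulated read starts, so that every window has the same
expected RC for a uniformly sequenced sample.

The number of simulated starts per window is

    n_w = ceil(E * U_sim / R_total)

where ``E`` is the target expected RC per window (default 150), ``U_sim``
the genome-wide count of uniquely mappable simulated reads, and
``R_total`` the sample's total retained reads: drawing ``R_total`` reads
uniformly over ``U_sim`` mappable starts then lands ``E`` reads per window
in expectation.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_EXPECTED_RC = 150

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _load_sequences(reference) -> dict[str, str]:
    """Accept a FASTA path or a {name: sequence} mapping."""
    if isinstance(reference, dict):
        return {str(k): str(v) for k, v in reference.items()}
    import pyfaidx

    fa = pyfaidx.Fasta(str(reference))
    return {name: str(fa[name][:]) for name in fa.keys()}


@dataclass
class MappabilityTrack:
    """Start coordinates of uniquely re-mappable simulated reads.

    ``positions[chrom]`` holds 0-based start coordinates, strictly
    increasing; ``total_sim_reads`` is U_sim, the genome-wide count.
    """

    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    read_length: int

    @property
    def total_sim_reads(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


@dataclass
class ReadCountTrack:
    """Per-window counts for one sample (raw integers or corrected reals)."""

    sample: str
    counts: np.ndarray
    gc: np.ndarray
    usable: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if not (len(self.counts) == len(self.gc) == len(self.usable)):
            raise ValueError("counts, gc and usable must have equal length")
        if np.any(self.counts[self.usable] < 0):
            raise ValueError("negative read counts")

    def copy_with(self, counts=None, usable=None) -> "ReadCountTrack":
        return ReadCountTrack(
            self.sample,
            self.counts if counts is None else counts,
            self.gc,
            self.usable if usable is None else usable,
        )


def simulate_mappability(reference, read_length: int, step: int = 1) -> MappabilityTrack:
    """Census-based stand-in for remapping simulated reads to the genome.

    Every ``read_length``-mer starting on the ``step`` grid is retained iff
    it occurs exactly once in the reference considering both strands (the
    forward census of the k-mer plus the census of its reverse complement).
    Substrings containing N are unmappable and never retained.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    seqs = _load_sequences(reference)
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise ValueError("empty or invalid reference")

    census: Counter = Counter()
    for seq in seqs.values():
        s = seq.upper()
        for i in range(len(s) - read_length + 1):
            kmer = s[i : i + read_length]
            if "N" not in kmer:
                census[kmer] += 1

    positions: dict[str, np.ndarray] = {}
    for name, seq in seqs.items():
        s = seq.upper()
        keep = []
        for i in range(0, len(s) - read_length + 1, step):
            kmer = s[i : i + read_length]
            if "N" in kmer:
                continue
            rc = _revcomp(kmer)
            occ = census[kmer] + (census[rc] if rc != kmer else 0)
            if occ == 1:
                keep.append(i)
        positions[name] = np.asarray(keep, dtype=np.int64)

    track = MappabilityTrack(
        positions=positions,
        chrom_lengths={name: len(seq) for name, seq in seqs.items()},
        read_length=read_length,
    )
    if track.total_sim_reads == 0:
        warnings.warn("no uniquely mappable positions retained", stacklevel=2)
    return track


def build_windows(
    mapp: MappabilityTrack,
    expected_rc: int = DEFAULT_EXPECTED_RC,
    sample_total_reads: int | None = None,
) -> pd.DataFrame:
    """Tile each chromosome into equal-expected-RC windows.

    Returns a DataFrame with columns ``chrom, start, end, n_sim, partial``
    (0-based half-open coordinates).  Window boundaries sit at the midpoint
    between the last simulated start of one window and the first of the
    next; chromosome ends close the terminal windows.  A trailing remainder
    with fewer than ``n_w`` starts becomes a final window flagged partial.
    Metadata (expected_rc, read_length, u_sim, n_w) is stored in ``.attrs``.
    """
    if expected_rc < 1:
        raise ValueError("expected_rc must be >= 1")
    u_sim = mapp.total_sim_reads
    if sample_total_reads is None:
        sample_total_reads = u_sim
    if sample_total_reads < expected_rc:
        raise ValueError("sample_total_reads must be >= expected_rc")
    n_w = math.ceil(expected_rc * u_sim / sample_total_reads)
    if n_w < 1:
        raise ValueError("computed n_w < 1; check expected_rc / total reads")

    rows = []
    for chrom, pos in mapp.positions.items():
        length = mapp.chrom_lengths[chrom]
        if len(pos) == 0:
            continue
        if len(pos) < n_w:
            warnings.warn(
                f"{chrom}: fewer than n_w={n_w} mappable positions; single partial window",
                stacklevel=2,
            )
        chunks = [pos[k : k + n_w] for k in range(0, len(pos), n_w)]
        bounds = [0]
        for a, b in zip(chunks[:-1], chunks[1:]):
            bounds.append(int((a[-1] + b[0] + 1) // 2))
        bounds.append(length)
        for t, chunk in enumerate(chunks):
            rows.append(
                (chrom, bounds[t], bounds[t + 1], len(chunk), len(chunk) < n_w)
            )

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sim", "partial"])
    df.attrs.update(
        expected_rc=int(expected_rc),
        read_length=int(mapp.read_length),
        u_sim=int(u_sim),
        n_w=int(n_w),
    )
    return df


def _gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def count_reads(
    alignments,
    windows: pd.DataFrame,
    mapq_min: int = 1,
    reference=None,
    sample: str | None = None,
) -> ReadCountTrack:
    """Count retained reads per window by leftmost mapped base.

    Retained reads are primary, mapped, MAPQ >= ``mapq_min`` (default 1,
    i.e. uniquely mapped for most aligners); properly paired fragments are
    counted once, by their leftmost read.  Per-window GC is the mean GC
    fraction of retained read sequences, falling back to the reference GC
    of the window when no reads land in it (requires ``reference``).
    """
    import pysam

    per_chrom: dict[str, dict] = {}
    for chrom, sub in windows.groupby("chrom", sort=False):
        per_chrom[chrom] = {
            "starts": sub["start"].to_numpy(),
            "ends": sub["end"].to_numpy(),
            "index": sub.index.to_numpy(),
        }

    n = len(windows)
    counts = np.zeros(n, dtype=np.int64)
    gc_sum = np.zeros(n, dtype=float)
    gc_n = np.zeros(n, dtype=np.int64)
    unmatched: set[str] = set()

    if sample is None:
        sample = Path(str(alignments)).stem if not hasattr(alignments, "fetch") else "sample"

    af = alignments if hasattr(alignments, "fetch") else pysam.AlignmentFile(str(alignments))
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_qcfail or read.mapping_quality < mapq_min:
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    continue
                # count the fragment once, by its leftmost read
                if read.next_reference_start < read.reference_start:
                    continue
                if (
                    read.next_reference_start == read.reference_start
                    and not read.is_read1
                ):
                    continue
            chrom = read.reference_name
            if chrom not in per_chrom:
                unmatched.add(chrom)
                continue
            tab = per_chrom[chrom]
            pos = read.reference_start
            k = int(np.searchsorted(tab["starts"], pos, side="right")) - 1
            if k < 0 or pos >= tab["ends"][k]:
                continue
            i = tab["index"][k]
            counts[i] += 1
            if read.query_sequence:
                g = _gc_fraction(read.query_sequence)
                if not math.isnan(g):
                    gc_sum[i] += g
                    gc_n[i] += 1
    finally:
        if af is not alignments:
            af.close()

    if unmatched:
        raise ValueError(
            "alignment contigs absent from windows: " + ", ".join(sorted(unmatched))
        )

    gc = np.full(n, np.nan)
    has = gc_n > 0
    gc[has] = gc_sum[has] / gc_n[has]
    if not np.all(has):
        if reference is not None:
            seqs = _load_sequences(reference)
            for i in np.nonzero(~has)[0]:
                row = windows.iloc[i]
                seq = seqs.get(row["chrom"], "")[row["start"] : row["end"]]
                gc[i] = _gc_fraction(seq) if seq else np.nan
        # windows with neither reads nor reference stay NaN -> unusable

    usable = ~windows["partial"].to_numpy() & np.isfinite(gc)
    return ReadCountTrack(sample=sample, counts=counts, gc=gc, usable=usable)
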