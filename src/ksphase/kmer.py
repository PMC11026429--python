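"""k-mer based genome-size estimation.

Genome size is estimated from the k-mer multiplicity spectrum of shotgun
reads as (total k-mer instances) / (depth of the homozygous-coverage peak):
every genomic position contributes roughly coverage-many k-mer instances, so
dividing by the per-copy depth recovers the number of distinct genomic k-mer
positions.  Counting is strand-canonical (lexicographic minimum of a k-mer
and its reverse complement) and the peak is found automatically as the
smoothed argmax of the spectrum above an error-multiplicity cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass
class KmerHistogram:
    """Multiplicity spectrum: number of distinct k-mers at each multiplicity."""

    k: int
    counts: dict[int, int]

    def __post_init__(self):
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("k-mer counts must be >= 0")

    @property
    def total_kmers(self) -> int:
        """Total k-mer instances, Σ multiplicity × count."""
        return int(sum(m * c for m, c in self.counts.items()))

    @property
    def distinct_kmers(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class GenomeSizeEstimate:
    total_kmers: int
    total_kmers_above_cutoff: int
    peak_depth: int
    size_bases: float
    error_cutoff: int


def count_kmers(reads, k: int) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram of a read set.

    k-mers and their reverse complements are collapsed; reads shorter than
    k contribute nothing, and windows containing non-ACGT characters are
    skipped.  Raises if no read yields a k-mer.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    reads = list(reads)
    if not reads:
        raise ValueError("no reads supplied")
    # join all reads with sentinel separators so windows never straddle a
    # read boundary, then encode in one pass
    blob = "\n".join(reads)
    codes = _BASE_CODE[np.frombuffer(blob.encode("ascii"), dtype=np.uint8)]
    if 2 * k > 62:
        raise ValueError(f"k={k} too large for packed counting (max 31)")
    n = len(codes)
    if n < k:
        raise ValueError(f"all reads shorter than k={k}")
    n_windows = n - k + 1
    # windows containing a separator or non-ACGT byte are invalid; one
    # cumulative sum gives per-window bad-byte counts without k passes
    cs = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(codes < 0, out=cs[1:])
    valid = (cs[k:] - cs[:-k]) == 0
    # 2-bit pack forward and reverse-complement k-mers (garbage bits in
    # invalid windows are masked out afterwards)
    fwd = np.zeros(n_windows, dtype=np.int64)
    rev = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        base = codes[j : j + n_windows]
        fwd |= (base & 3) << (2 * (k - 1 - j))
        rev |= ((3 - base) & 3) << (2 * j)
    canonical = np.minimum(fwd, rev)[valid]
    if canonical.size == 0:
        raise ValueError(f"all reads shorter than k={k}")
    _, mults = np.unique(canonical, return_counts=True)
    spectrum = np.bincount(mults)
    counts = {int(m): int(c) for m, c in enumerate(spectrum) if m >= 1 and c > 0}
    return KmerHistogram(k=k, counts=counts)


def find_peak(hist: KmerHistogram, error_cutoff: int = 3) -> int:
    """Depth of the homozygous-coverage peak.

    Applies a centered 3-bin moving average to the dense spectrum, then
    takes the argmax over multiplicities above ``error_cutoff``.  Ties are
    broken toward the multiplicity with the larger raw count, then toward
    the lower multiplicity.
    """
    if not hist.counts:
        raise ValueError("empty k-mer histogram")
    max_m = max(hist.counts)
    dense = np.zeros(max_m + 2, dtype=float)
    for m, c in hist.counts.items():
        dense[m] = c
    smoothed = np.convolve(dense, np.ones(3) / 3.0, mode="same")
    candidates = [m for m in range(error_cutoff + 1, max_m + 2)]
    candidates = [m for m in candidates if smoothed[m] > 0]
    if not candidates:
        raise ValueError(
            f"no k-mer mass above the error cutoff ({error_cutoff})"
        )
    best = max(candidates, key=lambda m: (smoothed[m], dense[m], -m))
    return int(best)


def estimate_size(
    hist: KmerHistogram,
    peak_depth: int | None = None,
    error_cutoff: int = 3,
    exclude_error_mass: bool = True,
) -> GenomeSizeEstimate:
    """Genome size in bases: total k-mer instances / homozygous peak depth.

    By default the numerator excludes instances at multiplicities at or
    below ``error_cutoff`` (sequencing-error k-mers inflate the total);
    both totals are reported.
    """
    if peak_depth is None:
        peak_depth = find_peak(hist, error_cutoff=error_cutoff)
    if peak_depth <= 0:
        raise ValueError(f"peak depth must be positive, got {peak_depth}")
    total = hist.total_kmers
    above = int(
        sum(m * c for m, c in hist.counts.items() if m > error_cutoff)
    )
    numerator = above if exclude_error_mass else total
    return GenomeSizeEstimate(
        total_kmers=total,
        total_kmers_above_cutoff=above,
        peak_depth=int(peak_depth),
        size_bases=numerator / peak_depth,
        error_cutoff=error_cutoff,
    )


def read_histogram_tsv(path) -> KmerHistogram:
    """Load a 2-column ``multiplicity<TAB>count`` histogram (k unknown → 0)."""
    counts: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            if lineno == 1 and not parts[0].lstrip("-").isdigit():
                continue  # header row
            m, c = int(parts[0]), int(parts[1])
            counts[m] = counts.get(m, 0) + c
    return KmerHistogram(k=0, counts=counts)
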