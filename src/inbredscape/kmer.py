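"""k-mer spectrum construction and peak-depth genome-size estimation.

The estimator is the classic coverage-peak method: count canonical
k-mers in the reads, locate the modal multiplicity (the sequencing depth
of single-copy sequence), discard the low-multiplicity error tail, and
divide the remaining k-mer instances by the modal depth.  k-mers are
packed 2 bits/base into int64 words so whole read sets are processed
with vectorised numpy passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


@dataclass
class KmerHistogram:
    """Multiplicity spectrum of canonical k-mers.

    ``counts`` maps multiplicity -> number of distinct k-mers seen that
    many times; ``total_kmers`` is the number of counted k-mer instances.
    """

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tdistinct_kmers\n")
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int) -> "KmerHistogram":
        counts = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                m, c = line.split()
                counts[int(m)] = int(c)
        return cls(k=k, counts=counts)


def _encode_batch(reads: list[str], k: int) -> np.ndarray:
    """Canonical k-mer codes (int64) for a batch of equal-length handling."""
    out = []
    # group by length so windows vectorise as a matrix per length class
    by_len: dict[int, list[str]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r)
    for L, grp in by_len.items():
        if L < k:
            continue
        raw = np.frombuffer("".join(grp).encode(), dtype=np.uint8).reshape(len(grp), L)
        codes = _CODE[raw]
        valid_base = codes != 255
        codes = np.where(valid_base, codes, 0)
        n_win = L - k + 1
        fwd = np.zeros((len(grp), n_win), dtype=np.int64)
        rev = np.zeros((len(grp), n_win), dtype=np.int64)
        ok = np.ones((len(grp), n_win), dtype=bool)
        for j in range(k):
            col = codes[:, j:j + n_win].astype(np.int64)
            fwd |= col << (2 * (k - 1 - j))
            rev |= (3 - col) << (2 * j)
            ok &= valid_base[:, j:j + n_win]
        canon = np.minimum(fwd, rev)
        out.append(canon[ok])
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out)


def kmer_histogram(reads: Iterable[str], k: int = 17, batch_size: int = 200_000) -> KmerHistogram:
    """Count canonical k-mers (lexicographic min of k-mer and its reverse
    complement) across a read set; windows containing N are skipped.

    Parameters
    ----------
    reads : iterable of sequence strings over {A,C,G,T,N}
    k : odd k-mer size in [11, 31] (odd k makes canonicalisation unambiguous)
    """
    # odd k keeps canonicalisation unambiguous (no self-reverse-complement
    # k-mers); sizes below 11 are only sensible for toy examples
    if k % 2 == 0 or not 3 <= k <= 31:
        raise ValueError(f"k must be odd and in [3, 31], got {k}")
    chunks: list[np.ndarray] = []
    batch: list[str] = []
    n_reads = 0
    for read in reads:
        n_reads += 1
        batch.append(read)
        if len(batch) >= batch_size:
            chunks.append(_encode_batch(batch, k))
            batch = []
    if batch:
        chunks.append(_encode_batch(batch, k))
    if n_reads == 0:
        raise ValueError("empty read set")
    allk = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    if allk.size == 0:
        raise ValueError(f"no read is as long as k={k}")
    _, mults = np.unique(allk, return_counts=True)
    mvals, mcounts = np.unique(mults, return_counts=True)
    return KmerHistogram(k=k, counts={int(m): int(c) for m, c in zip(mvals, mcounts)})


def _first_local_minimum(mult: np.ndarray, cnt: np.ndarray) -> int:
    """Error cutoff: the multiplicity at the first local minimum of the
    spectrum (the trough between the error tail and the coverage peak)."""
    for i in range(1, len(cnt) - 1):
        if cnt[i] <= cnt[i - 1] and cnt[i] <= cnt[i + 1]:
            return int(mult[i])
    return 0


def estimate_genome_size(hist: KmerHistogram, error_cutoff: int | None = None) -> int:
    """Peak-depth genome size: usable k-mer instances / modal multiplicity.

    ``error_cutoff`` defaults to the first local minimum of the spectrum;
    multiplicities at or below it are treated as sequencing-error k-mers
    and excluded from both the numerator and the mode search.

    Raises ValueError when no coverage mode exists above the cutoff
    (e.g. a spectrum that is pure low-multiplicity noise).
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    mult = np.array(sorted(hist.counts), dtype=np.int64)
    cnt = np.array([hist.counts[int(m)] for m in mult], dtype=np.int64)
    if error_cutoff is None:
        error_cutoff = _first_local_minimum(mult, cnt)
    keep = mult > error_cutoff
    if not keep.any():
        raise ValueError(f"no k-mer multiplicity above error cutoff {error_cutoff}")
    mult_k, cnt_k = mult[keep], cnt[keep]
    modal = int(mult_k[np.argmax(cnt_k)])
    if (error_cutoff == 0 and len(cnt) >= 2 and modal == int(mult[0])
            and bool(np.all(np.diff(cnt) <= 0))):
        # monotone decreasing spectrum: pure error noise, no coverage peak
        raise ValueError("no detectable coverage mode above the error tail; "
                         "spectrum is monotone low-multiplicity noise")
    usable = int((mult_k * cnt_k).sum())
    return int(round(usable / modal))


def half_depth_shoulder(hist: KmerHistogram, error_cutoff: int | None = None) -> float:
    """Descriptive heterozygosity signature: mass near half the modal depth
    relative to mass at the modal depth (low values = low heterozygosity)."""
    mult = np.array(sorted(hist.counts), dtype=np.int64)
    cnt = np.array([hist.counts[int(m)] for m in mult], dtype=np.int64)
    if error_cutoff is None:
        error_cutoff = _first_local_minimum(mult, cnt)
    keep = mult > error_cutoff
    if not keep.any():
        return float("nan")
    modal = int(mult[keep][np.argmax(cnt[keep])])
    half = modal // 2
    if half <= error_cutoff:
        return float("nan")
    window = lambda c: cnt[(mult >= c - 1) & (mult <= c + 1)].sum()  # noqa: E731
    peak_mass = window(modal)
    return float(window(half) / peak_mass) if peak_mass else float("nan")


def read_sequences(path: str | Path) -> Iterable[str]:
    """Sequences from FASTA or FASTQ, format sniffed from the first byte."""
    from Bio import SeqIO

    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq)
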