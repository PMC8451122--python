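"""Windowed tetranucleotide-signature correlation profiling.

Oligonucleotide usage is a genome-wide signature: 4-mer frequency vectors
of fragments from one replicon correlate strongly with the whole-replicon
vector, while horizontally acquired or host-adapted segments stand out as
local dips in that correlation. This module slices a genome into
overlapping fragments (default 10 kb window, 1 kb step), computes each
fragment's 256-dimensional tetranucleotide frequency vector, z-scores it
across the 256 components, and reports the Pearson correlation of each
fragment against the whole-genome signature (``r_self``) and, optionally,
against a host genome's signature (``r_host``).

The genome is padded by wrap-around on both ends so every 1 kb step tile
is represented by a full-width fragment centered on it: a genome of length
L yields ``ceil(L / step)`` fragments regardless of window size. Wrap
padding preserves genome-wide composition exactly, which mirrored or
random padding would not.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from phageadapt.io import GenomeSequence, reverse_complement

#: The 256 tetranucleotides in lexicographic order "AAAA".."TTTT".
TETRAMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)
TETRAMER_INDEX: dict[str, int] = {t: i for i, t in enumerate(TETRAMERS)}

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class DegenerateSignatureError(ValueError):
    """A constant vector has no z-score and no correlation."""


@dataclass(frozen=True)
class TetraVector:
    """Raw overlapping 4-mer counts of one sequence.

    ``counts`` is indexed by :data:`TETRAMERS`; windows containing an N are
    skipped, so ``counts.sum() == n_windows_counted`` and, for an N-free
    sequence of length L >= 4, ``n_windows_counted == L - 3``.
    """

    counts: np.ndarray
    n_windows_counted: int

    def frequencies(self) -> np.ndarray:
        """Counts normalized to frequencies (sum 1); requires >= 1 window."""
        if self.n_windows_counted == 0:
            raise DegenerateSignatureError(
                "no countable 4-mer windows (sequence too short or all-N)"
            )
        return self.counts / self.n_windows_counted


@dataclass
class SignatureProfile:
    """Per-fragment z-scored signatures and correlation tracks."""

    window_bp: int
    step_bp: int
    fragment_index: np.ndarray  # 1-based
    fragment_center_bp: np.ndarray  # 1-based
    zvec: np.ndarray  # (n_fragments, 256)
    r_self: np.ndarray
    r_host: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.fragment_index)


def count_tetra(seq: str) -> TetraVector:
    """Count overlapping 4-mers on the forward strand.

    The width-4 window slides by 1; any window containing a non-ACGT
    residue is skipped and not counted in ``n_windows_counted``.
    """
    if len(seq) < 4:
        raise ValueError(f"sequence of length {len(seq)} has no 4-mer window")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    c0 = codes[:-3]
    c1 = codes[1:-2]
    c2 = codes[2:-1]
    c3 = codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    idx = ((c0 * 4 + c1) * 4 + c2) * 4 + c3
    counts = np.bincount(idx[valid], minlength=256).astype(np.int64)
    return TetraVector(counts=counts, n_windows_counted=int(valid.sum()))


def zscore(v: np.ndarray) -> np.ndarray:
    """Z-score a vector across its components (population sd).

    The output has mean 0 and population standard deviation 1; a constant
    input has no signature and raises :class:`DegenerateSignatureError`.
    """
    v = np.asarray(v, dtype=float)
    sd = v.std()  # population sd (ddof=0)
    if sd == 0:
        raise DegenerateSignatureError("constant vector has zero standard deviation")
    return (v - v.mean()) / sd


def slice_fragments(
    g: GenomeSequence, window_bp: int = 10_000, step_bp: int = 1_000
) -> list[tuple[int, int, str]]:
    """Slice a genome into window_bp fragments, one per step_bp tile.

    Returns ``(fragment_index, center_bp, subsequence)`` triples. Fragment i
    (1-based) is centered on the midpoint of the i-th step tile; the genome
    is extended on both ends by wrap-around so every fragment has exactly
    ``window_bp`` residues. A genome of length L yields ``ceil(L / step_bp)``
    fragments, so each step tile of the genome is represented by one
    full-width fragment.
    """
    L = len(g)
    if step_bp < 1:
        raise ValueError("step_bp must be >= 1")
    if window_bp > L:
        raise ValueError(
            f"window_bp ({window_bp}) exceeds genome length ({L}); "
            "choose a window no longer than the genome"
        )
    n_fragments = math.ceil(L / step_bp)
    # triple concatenation makes wrap-around slicing a plain substring
    # (window_bp <= L guarantees any fragment fits inside it)
    ext = g.residues * 3
    out = []
    for i in range(1, n_fragments + 1):
        tile_start = (i - 1) * step_bp + 1
        tile_end = min(i * step_bp, L)
        center = (tile_start + tile_end) // 2
        frag_start0 = (center - 1) - window_bp // 2  # 0-based, may be negative
        frag = ext[L + frag_start0 : L + frag_start0 + window_bp]
        out.append((i, center, frag))
    return out


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateSignatureError("constant vector has no correlation")
    r = float(np.corrcoef(a, b)[0, 1])
    # clip numerical overshoot
    return max(-1.0, min(1.0, r))


def _signature(seq: str, strand: str) -> np.ndarray:
    """Z-scored 4-mer frequency vector of a sequence."""
    tv = count_tetra(seq)
    counts = tv.counts
    n = tv.n_windows_counted
    if strand == "both":
        rc = count_tetra(reverse_complement(seq))
        counts = counts + rc.counts
        n += rc.n_windows_counted
    if n == 0:
        raise DegenerateSignatureError("no countable 4-mer windows")
    return zscore(counts / n)


def signature_profile(
    phage: GenomeSequence,
    host: GenomeSequence | None = None,
    window_bp: int = 10_000,
    step_bp: int = 1_000,
    strand: str = "forward",
) -> SignatureProfile:
    """Correlation profile of fragment signatures against whole genomes.

    For each fragment, ``r_self`` is the Pearson correlation between the
    fragment's z-scored 4-mer frequency vector and the whole-phage-genome
    vector; ``r_host`` is the analogous correlation against the whole host
    genome when one is supplied. ``strand="both"`` pools forward and
    reverse-complement counts for strand-symmetric signatures.
    """
    if strand not in ("forward", "both"):
        raise ValueError(f"strand must be 'forward' or 'both', got {strand!r}")
    ref_self = _signature(phage.residues, strand)
    ref_host = _signature(host.residues, strand) if host is not None else None

    fragments = slice_fragments(phage, window_bp=window_bp, step_bp=step_bp)
    n = len(fragments)
    idx = np.empty(n, dtype=np.int64)
    centers = np.empty(n, dtype=np.int64)
    zvecs = np.empty((n, 256), dtype=float)
    r_self = np.empty(n, dtype=float)
    r_host = np.empty(n, dtype=float) if ref_host is not None else None
    for k, (i, center, frag) in enumerate(fragments):
        z = _signature(frag, strand)
        idx[k] = i
        centers[k] = center
        zvecs[k] = z
        r_self[k] = pearson(z, ref_self)
        if r_host is not None:
            r_host[k] = pearson(z, ref_host)
    return SignatureProfile(
        window_bp=window_bp,
        step_bp=step_bp,
        fragment_index=idx,
        fragment_center_bp=centers,
        zvec=zvecs,
        r_self=r_self,
        r_host=r_host,
    )


def locate_anomaly(profile: SignatureProfile, k: float = 2.0) -> dict:
    """Locate the compositional anomaly in a correlation profile.

    Returns the fragment of minimum ``r_self`` (first occurrence on ties)
    and the dip span: the maximal contiguous run of fragments, containing
    the minimum, whose ``r_self`` falls below ``median - k * MAD`` (MAD =
    median absolute deviation). An empty dip span (``None``) means no
    fragment falls below the robust threshold.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    r = profile.r_self
    imin = int(np.argmin(r))  # first occurrence
    med = float(np.median(r))
    mad = float(np.median(np.abs(r - med)))
    thr = med - k * mad
    below = r < thr
    dip_span = None
    if below[imin]:
        lo = imin
        while lo > 0 and below[lo - 1]:
            lo -= 1
        hi = imin
        while hi < len(r) - 1 and below[hi + 1]:
            hi += 1
        dip_span = (int(profile.fragment_index[lo]), int(profile.fragment_index[hi]))
    return {
        "min_fragment_index": int(profile.fragment_index[imin]),
        "min_r_self": float(r[imin]),
        "dip_span": dip_span,
    }
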