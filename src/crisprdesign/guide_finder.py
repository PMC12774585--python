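"""SpCas9 target-site enumeration and genome-wide off-target counting.

Site geometry
-------------
A site is a 20-nt protospacer immediately 5′ of an NGG PAM, on either strand.
``pam_start`` is the plus-strand coordinate of the PAM's first base *read in
the site's own 5′→3′ direction*: for a plus-strand site the PAM occupies
``[pam_start, pam_start+3)``; for a minus-strand site (plus-strand pattern
``CCN`` + 20 nt) the PAM occupies ``[pam_start-2, pam_start+1)`` and
``pam_start`` is the coordinate of the N.

SpCas9 cuts bluntly between protospacer bases 17 and 18 (3 bp 5′ of the
PAM). ``cut_pos`` is the plus-strand coordinate of the protospacer's 18th
base — the base immediately 3′ of the cut on the protospacer strand — which
works out to ``pam_start − 3`` on '+' and ``pam_start + 3`` on '−'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import GenomeAssembly, revcomp

__all__ = [
    "GuideSite",
    "count_offtargets",
    "cut_position",
    "scan_guides",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def cut_position(pam_start: int, strand: str) -> int:
    """Blunt-cut coordinate for a PAM at *pam_start* on *strand*."""
    if strand == "+":
        return pam_start - 3
    if strand == "-":
        return pam_start + 3
    raise ValueError(f"bad strand {strand!r}")


@dataclass(frozen=True)
class GuideSite:
    """A candidate Cas9 target: protospacer + PAM with genomic context."""

    protospacer: str
    pam: str
    strand: str
    contig: str
    pam_start: int
    cut_pos: int
    anchor_distance: int
    efficiency: float = 0.0
    offtargets: dict[int, int] = field(default_factory=dict, compare=False)
    overlaps_anchor: bool = False

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.cut_pos != cut_position(self.pam_start, self.strand):
            raise ValueError("cut_pos inconsistent with pam_start/strand")

    @property
    def ot_total(self) -> int:
        """Sum of mismatched off-target counts (1..max mismatch)."""
        return sum(v for m, v in self.offtargets.items() if m > 0)

    @property
    def has_exact_offtarget(self) -> bool:
        return self.offtargets.get(0, 0) > 0

    def with_score(self, efficiency: float) -> "GuideSite":
        return replace(self, efficiency=efficiency)

    def with_offtargets(self, counts: dict[int, int]) -> "GuideSite":
        return replace(self, offtargets=dict(counts))


def _sites_in_span(seq: str, contig: str, lo: int, hi: int,
                   protospacer_len: int) -> list[tuple[str, str, str, int]]:
    """All (protospacer, pam, strand, pam_start) whose PAM 'GG'/'CC' core
    lies so the full site fits inside the contig and the cut falls in
    [lo, hi]. Sites containing N are excluded by the caller."""
    out = []
    n = len(seq)
    # plus strand: protospacer [p-L, p), PAM [p, p+3) with seq[p+1:p+3]=="GG"
    for p in range(protospacer_len, n - 2):
        if seq[p + 1] == "G" and seq[p + 2] == "G":
            cut = p - 3
            if lo <= cut <= hi:
                out.append((seq[p - protospacer_len : p], seq[p : p + 3], "+", p))
    # minus strand: plus-strand pattern CCN at [q, q+3), protospacer
    # [q+3, q+3+L); pam_start = q+2
    for q in range(0, n - protospacer_len - 2):
        if seq[q] == "C" and seq[q + 1] == "C":
            pam_start = q + 2
            cut = pam_start + 3
            if lo <= cut <= hi:
                proto = revcomp(seq[q + 3 : q + 3 + protospacer_len])
                pam = revcomp(seq[q : q + 3])
                out.append((proto, pam, "-", pam_start))
    return out


def scan_guides(
    assembly: GenomeAssembly,
    contig: str,
    anchor_pos: int,
    window_bp: int,
    protospacer_len: int = 20,
    pam_pattern: str = "NGG",
) -> list[GuideSite]:
    """Enumerate Cas9 sites on both strands whose cut position lies within
    ``[anchor_pos − window_bp, anchor_pos + window_bp]``.

    Sites containing N are excluded. The list is sorted by
    ``|anchor_distance|`` ascending, ties broken by genomic position then
    strand ('+' before '−'). A window running past the contig ends is
    clipped with a warning, not an error.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if pam_pattern != "NGG":
        raise NotImplementedError("only the NGG PAM is supported")
    seq = assembly.sequences[contig]
    if not (0 <= anchor_pos <= len(seq)):
        raise IndexError(f"anchor {anchor_pos} outside contig {contig!r}")
    lo, hi = anchor_pos - window_bp, anchor_pos + window_bp
    if lo < 0 or hi > len(seq):
        warnings.warn(
            f"guide window [{lo}, {hi}] clipped to contig bounds "
            f"[0, {len(seq)}]",
            stacklevel=2,
        )
        lo, hi = max(lo, 0), min(hi, len(seq))
    sites = []
    for proto, pam, strand, pam_start in _sites_in_span(
        seq, contig, lo, hi, protospacer_len
    ):
        if "N" in proto or "N" in pam:
            continue
        cut = cut_position(pam_start, strand)
        # anchor codon occupies [anchor, anchor+3) on the plus strand for
        # '+' genes; overlap is approximated by the protospacer+PAM span
        if strand == "+":
            span = (pam_start - protospacer_len, pam_start + 3)
        else:
            span = (pam_start - 2, pam_start + 1 + protospacer_len)
        overlaps = span[0] < anchor_pos + 3 and anchor_pos < span[1]
        sites.append(
            GuideSite(
                protospacer=proto,
                pam=pam,
                strand=strand,
                contig=contig,
                pam_start=pam_start,
                cut_pos=cut,
                anchor_distance=cut - anchor_pos,
                overlaps_anchor=overlaps,
            )
        )
    sites.sort(key=lambda s: (abs(s.anchor_distance), s.pam_start, s.strand))
    return sites


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def count_offtargets(
    site: GuideSite, assembly: GenomeAssembly, max_mismatch: int = 3
) -> dict[int, int]:
    """Count genomic NGG-adjacent 20-mers at each Hamming distance 0..max.

    Both strands of every contig are scanned; the site's own locus is
    excluded from the distance-0 bin. PAM positions containing N are
    skipped; N inside a window never matches any protospacer base, so
    windows with N simply fall outside ``max_mismatch`` in practice.
    """
    L = len(site.protospacer)
    proto = _encode(site.protospacer)
    proto_rc = _encode(revcomp(site.protospacer))
    counts = {m: 0 for m in range(max_mismatch + 1)}
    G, C, N = ord("G"), ord("C"), ord("N")
    for contig, seq in assembly.sequences.items():
        arr = _encode(seq)
        n = len(arr)
        if n < L + 3:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)

        # plus strand: pam_start p has GG at [p+1, p+3), N-base at p,
        # protospacer window at p-L
        gg = np.flatnonzero((arr[1:-1] == G) & (arr[2:] == G))  # = pam_start
        gg = gg[(gg >= L) & (arr[gg] != N)]
        if gg.size:
            mm = np.count_nonzero(windows[gg - L] != proto, axis=1)
            for p, m in zip(gg, mm):
                if m > max_mismatch:
                    continue
                if (
                    m == 0
                    and contig == site.contig
                    and site.strand == "+"
                    and int(p) == site.pam_start
                ):
                    continue
                counts[int(m)] += 1

        # minus strand: plus-strand CCN at [q, q+3), pam_start = q+2,
        # protospacer window at q+3 compared against revcomp(protospacer)
        cc = np.flatnonzero((arr[:-1] == C) & (arr[1:] == C))
        cc = cc[(cc + 3 + L <= n) & (arr[np.minimum(cc + 2, n - 1)] != N)]
        if cc.size:
            mm = np.count_nonzero(windows[cc + 3] != proto_rc, axis=1)
            for q, m in zip(cc, mm):
                if m > max_mismatch:
                    continue
                if (
                    m == 0
                    and contig == site.contig
                    and site.strand == "-"
                    and int(q) + 2 == site.pam_start
                ):
                    continue
                counts[int(m)] += 1
    return counts
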