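"""Amplification and sequencing primer proposal around a Cas9 cut site.

Primers are searched in four fixed distance windows measured from the cut
position to the primer's 5′ end: amplification primers 1000–1200 bp away on
each side (the resulting PCR product spans both homology arms), sequencing
primers 400–600 bp away (reading across each arm junction from inside the
product). Candidates are filtered on melting temperature, GC content,
homopolymer runs and 3′ self-complementarity, then ranked deterministically.

Melting temperatures come from Biopython's ``Bio.SeqUtils.MeltingTemp``:
the Wallace rule (``2(A+T) + 4(G+C)``) or nearest-neighbor thermodynamics
with the SantaLucia & Hicks (2004) unified parameter set, 50 mM Na+ and the
SantaLucia (1998) entropy salt correction, at 25 nM strand concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .genome_io import GenomeAssembly, extract_region, revcomp

__all__ = [
    "PrimerCandidate",
    "PrimerPair",
    "PrimerConfig",
    "melting_temp",
    "primer_windows",
    "pick_primer_pairs",
    "pick_sequencing_primers",
]

# distance (bp) from the cut position to the primer 5' end
FAR_WINDOW = (1000, 1200)   # amplification primers
NEAR_WINDOW = (400, 600)    # sequencing primers


class PrimerConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerConfig:
    """Primer search constraints. All fields overridable from the config file."""

    min_len: int = 18
    max_len: int = 27
    tm_min: float = 57.0
    tm_max: float = 63.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 4
    max_three_prime_selfcomp: int = 3
    tm_method: str = "nn"
    product_opt: int = 2200
    top_k: int = 5

    def validate(self) -> None:
        if self.min_len < 8 or self.max_len < self.min_len:
            raise PrimerConfigError("bad primer length bounds")
        if self.tm_min > self.tm_max:
            raise PrimerConfigError(
                f"impossible Tm range: min {self.tm_min} > max {self.tm_max}"
            )
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise PrimerConfigError("bad GC bounds")
        if self.tm_method not in ("nn", "wallace"):
            raise PrimerConfigError(f"unknown Tm method {self.tm_method!r}")


@dataclass(frozen=True)
class PrimerCandidate:
    """A single oligo, written 5'→3' on its own strand."""

    sequence: str
    genomic_start: int  # plus-strand coordinate of the 5' base
    strand: str
    tm: float
    gc: float
    role: str  # amplification | sequencing
    side: str  # upstream | downstream

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Plus-strand half-open interval covered by the oligo."""
        if self.strand == "+":
            return (self.genomic_start, self.genomic_start + self.length)
        return (self.genomic_start - self.length + 1, self.genomic_start + 1)


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate

    @property
    def product_size(self) -> int:
        """Amplicon length: from forward 5' start to reverse 5' end inclusive."""
        return self.reverse.genomic_start + 1 - self.forward.genomic_start

    @property
    def tm_delta(self) -> float:
        return abs(self.forward.tm - self.reverse.tm)


def melting_temp(sequence: str, method: str = "nn",
                 params: dict | None = None) -> float:
    """Melting temperature in °C by the Wallace rule or NN thermodynamics."""
    if len(sequence) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if set(sequence) - set("ACGT"):
        raise ValueError(f"non-ACGT base in {sequence!r}")
    params = params or {}
    if method == "wallace":
        return float(_mt.Tm_Wallace(sequence))
    if method == "nn":
        kwargs = dict(
            nn_table=_mt.DNA_NN4,  # SantaLucia & Hicks 2004 unified
            Na=50, K=0, Tris=0, Mg=0, dNTPs=0,
            saltcorr=5,            # dS += 0.368 (N-1) ln[Na+]
            dnac1=25, dnac2=25,
        )
        kwargs.update(params)
        return float(_mt.Tm_NN(sequence, **kwargs))
    raise ValueError(f"unknown Tm method {method!r}")


def gc_fraction(sequence: str) -> float:
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def max_homopolymer_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def three_prime_selfcomp(sequence: str, probe_len: int = 6) -> int:
    """Longest suffix of the 3' end that is reverse-complementary to any
    site within the oligo itself (a crude primer-dimer proxy)."""
    best = 0
    for k in range(1, min(probe_len, len(sequence)) + 1):
        tail = sequence[-k:]
        if revcomp(tail) in sequence:
            best = k
    return best


def primer_windows(
    cut_pos: int, locus_bounds: tuple[int, int], config: PrimerConfig | None = None
) -> dict[str, tuple[int, int]]:
    """The four 5'-end search windows around a cut position.

    Returns half-open plus-strand intervals keyed ``upstream-far``,
    ``upstream-near``, ``downstream-near``, ``downstream-far``; far windows
    (1000–1200 bp out) host amplification primers, near windows
    (400–600 bp out) sequencing primers. Windows are clipped to the locus;
    a fully excluded window comes back empty with a warning.
    """
    lo, hi = locus_bounds
    if not (lo <= cut_pos <= hi):
        raise ValueError(f"cut {cut_pos} outside locus [{lo}, {hi})")
    raw = {
        "upstream-far": (cut_pos - FAR_WINDOW[1], cut_pos - FAR_WINDOW[0]),
        "upstream-near": (cut_pos - NEAR_WINDOW[1], cut_pos - NEAR_WINDOW[0]),
        "downstream-near": (cut_pos + NEAR_WINDOW[0], cut_pos + NEAR_WINDOW[1]),
        "downstream-far": (cut_pos + FAR_WINDOW[0], cut_pos + FAR_WINDOW[1]),
    }
    out: dict[str, tuple[int, int]] = {}
    for name, (a, b) in raw.items():
        ca, cb = max(a, lo), min(b, hi)
        if ca >= cb:
            warnings.warn(f"primer window {name} lies outside the locus", stacklevel=2)
            out[name] = (cut_pos, cut_pos)  # empty
        else:
            if (ca, cb) != (a, b):
                warnings.warn(f"primer window {name} clipped to locus bounds",
                              stacklevel=2)
            out[name] = (ca, cb)
    return out


def _enumerate_candidates(
    assembly: GenomeAssembly,
    contig: str,
    window: tuple[int, int],
    strand: str,
    role: str,
    side: str,
    config: PrimerConfig,
    diagnostics: dict[str, int],
) -> list[PrimerCandidate]:
    """All oligos of configured lengths whose 5' end lies in *window*."""
    out: list[PrimerCandidate] = []
    contig_len = assembly.length(contig)
    for start in range(*window):
        for length in range(config.min_len, config.max_len + 1):
            if strand == "+":
                s, e = start, start + length
            else:
                s, e = start - length + 1, start + 1
            if s < 0 or e > contig_len:
                diagnostics["out_of_bounds"] += 1
                continue
            seq = extract_region(assembly, contig, s, e, strand)
            if "N" in seq:
                diagnostics["contains_N"] += 1
                continue
            gc = gc_fraction(seq)
            if not (config.gc_min <= gc <= config.gc_max):
                diagnostics["gc"] += 1
                continue
            if max_homopolymer_run(seq) > config.max_homopolymer:
                diagnostics["homopolymer"] += 1
                continue
            tm = melting_temp(seq, config.tm_method)
            if not (config.tm_min <= tm <= config.tm_max):
                diagnostics["tm"] += 1
                continue
            if three_prime_selfcomp(seq) > config.max_three_prime_selfcomp:
                diagnostics["three_prime_selfcomp"] += 1
                continue
            out.append(
                PrimerCandidate(
                    sequence=seq, genomic_start=start, strand=strand,
                    tm=round(tm, 2), gc=gc, role=role, side=side,
                )
            )
    return out


def pick_primer_pairs(
    assembly: GenomeAssembly,
    contig: str,
    windows: dict[str, tuple[int, int]],
    config: PrimerConfig | None = None,
) -> tuple[list[PrimerPair], dict[str, int]]:
    """Ranked amplification primer pairs from the far windows.

    Forward candidates sit on '+' with 5' ends in ``upstream-far``; reverse
    candidates on '−' with 5' ends in ``downstream-far``. Pairs are ranked
    by ``tm_delta`` ascending, then by closeness of the product size to the
    configured optimum, then by coordinates (fully deterministic). Returns
    the top-k pairs plus per-filter failure diagnostics.
    """
    config = config or PrimerConfig()
    config.validate()
    diag: dict[str, int] = {k: 0 for k in (
        "out_of_bounds", "contains_N", "gc", "homopolymer", "tm",
        "three_prime_selfcomp")}
    fwd = _enumerate_candidates(
        assembly, contig, windows["upstream-far"], "+", "amplification",
        "upstream", config, diag)
    rev = _enumerate_candidates(
        assembly, contig, windows["downstream-far"], "-", "amplification",
        "downstream", config, diag)
    pairs = [PrimerPair(f, r) for f in fwd for r in rev]
    pairs.sort(key=lambda p: (
        p.tm_delta,
        abs(p.product_size - config.product_opt),
        p.forward.genomic_start,
        p.reverse.genomic_start,
        p.forward.length,
        p.reverse.length,
    ))
    return pairs[: config.top_k], diag


def pick_sequencing_primers(
    assembly: GenomeAssembly,
    contig: str,
    windows: dict[str, tuple[int, int]],
    config: PrimerConfig | None = None,
) -> tuple[list[PrimerCandidate], dict[str, int]]:
    """Ranked single sequencing oligos from the near windows.

    Upstream sequencing primers read rightwards ('+'), downstream ones
    leftwards ('−'), both toward the cut. Ranked by closeness to the middle
    of the Tm range, then coordinates.
    """
    config = config or PrimerConfig()
    config.validate()
    diag: dict[str, int] = {k: 0 for k in (
        "out_of_bounds", "contains_N", "gc", "homopolymer", "tm",
        "three_prime_selfcomp")}
    ups = _enumerate_candidates(
        assembly, contig, windows["upstream-near"], "+", "sequencing",
        "upstream", config, diag)
    downs = _enumerate_candidates(
        assembly, contig, windows["downstream-near"], "-", "sequencing",
        "downstream", config, diag)
    tm_mid = (config.tm_min + config.tm_max) / 2
    key = lambda c: (abs(c.tm - tm_mid), c.genomic_start, c.length)  # noqa: E731
    out = sorted(ups, key=key)[: config.top_k] + sorted(downs, key=key)[: config.top_k]
    return out, diag
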