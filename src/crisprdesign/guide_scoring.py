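"""Position-weight efficiency scoring and composite ranking of guide sites.

The efficiency model is a plug-in 20x4 position-weight matrix: the score of
a protospacer is the sum of the weight of its base at each position. The
default matrix shipped with the package is a synthetic stand-in (see its
provenance header); any whitespace-delimited 20x4 table with an "A C G T"
header can be substituted. Ranking combines efficiency with off-target
burden under a fully deterministic composite key so output is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .guide_finder import GuideSite

__all__ = [
    "EfficiencyMatrix",
    "efficiency_score",
    "load_matrix",
    "default_matrix",
    "rank_guides",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class EfficiencyMatrix:
    """20 positions x 4 bases of real-valued weights."""

    weights: np.ndarray  # shape (20, 4), columns A C G T
    name: str = "unnamed"
    provenance: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (20, 4):
            raise ValueError(f"matrix must be 20x4, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("matrix contains non-finite weights")
        object.__setattr__(self, "weights", w)


def load_matrix(path: str | Path, name: str | None = None) -> EfficiencyMatrix:
    """Read a whitespace-delimited 20x4 matrix with an ``A C G T`` header.

    Lines starting with ``#`` are treated as provenance comments and kept.
    """
    path = Path(path)
    provenance_lines: list[str] = []
    rows: list[list[float]] = []
    header: list[str] | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance_lines.append(line.lstrip("# "))
            continue
        if header is None:
            header = line.split()
            if [b.upper() for b in header] != list(_BASES):
                raise ValueError(
                    f"matrix header must be 'A C G T', got {header!r}"
                )
            continue
        rows.append([float(x) for x in line.split()])
    if header is None or len(rows) != 20 or any(len(r) != 4 for r in rows):
        raise ValueError(f"matrix file {path} is not 20 rows x 4 columns")
    return EfficiencyMatrix(
        weights=np.array(rows),
        name=name or path.stem,
        provenance="\n".join(provenance_lines),
    )


def default_matrix() -> EfficiencyMatrix:
    """The packaged default matrix (a labelled synthetic stand-in)."""
    ref = resources.files("crisprdesign").joinpath("data/efficiency_matrix.tsv")
    with resources.as_file(ref) as path:
        return load_matrix(path, name="builtin-synthetic")


def efficiency_score(protospacer: str, matrix: EfficiencyMatrix) -> float:
    """Sum of per-position weights for the protospacer's bases."""
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    try:
        idx = [_BASE_INDEX[b] for b in protospacer]
    except KeyError as exc:
        raise ValueError(
            f"protospacer contains non-ACGT base {exc.args[0]!r}"
        ) from None
    return float(matrix.weights[np.arange(20), idx].sum())


def rank_guides(
    sites: list[GuideSite],
    matrix: EfficiencyMatrix | None = None,
    score: bool = True,
) -> list[GuideSite]:
    """Order guide sites best-first under the documented composite key.

    Sites carrying an exact off-target (``ot0 > 0``) are demoted to the end
    of the list and flagged (``has_exact_offtarget``), never silently
    removed — the user, not the tool, makes the final call. Within each
    group the key is: efficiency descending, then total mismatched
    off-targets ascending, then ``|anchor_distance|`` ascending; the sort
    is stable thereafter.
    """
    if matrix is None:
        matrix = default_matrix()
    if score:
        sites = [s.with_score(efficiency_score(s.protospacer, matrix)) for s in sites]
    return sorted(
        sites,
        key=lambda s: (
            s.has_exact_offtarget,
            -s.efficiency,
            s.ot_total,
            abs(s.anchor_distance),
        ),
    )
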