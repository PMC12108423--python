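"""Published worked example of consensus scoring, used in tests and docs.

Five top-ranked screening hits from a published three-fingerprint consensus
screen (Avalon, circular/ECFP6, PubChem substructure keys), as printed at
3-decimal precision: per-kind Euclidean distances, their z-score normalized
values, and the consensus average.  The raw distances depend on the
original proprietary library and toolkit and are carried for context only;
the (norms -> consensus) arithmetic is reproducible from these rows alone.

Note the printed consensus column was computed from *unrounded* normalized
scores, so re-averaging the 3-decimal norms can differ from the printed
consensus by up to ~0.002 in the last digit.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WorkedExampleRow", "WORKED_EXAMPLE", "CONSENSUS_CUTOFF"]

#: Consensus cutoff applied in the published screen (strictly below).
CONSENSUS_CUTOFF = -2.5


@dataclass(frozen=True)
class WorkedExampleRow:
    compound_id: str
    distances: dict[str, float]  # per-kind Euclidean distance, as printed
    norms: dict[str, float]  # per-kind z-score, as printed
    consensus_printed: float  # consensus average, as printed


_KINDS = ("avalon", "circular", "pubchem")

WORKED_EXAMPLE: tuple[WorkedExampleRow, ...] = tuple(
    WorkedExampleRow(
        compound_id=cid,
        distances=dict(zip(_KINDS, dists)),
        norms=dict(zip(_KINDS, norms)),
        consensus_printed=cons,
    )
    for cid, dists, norms, cons in [
        ("1", (9.747, 9.899, 9.747), (-3.345, -2.963, -2.733), -3.013),
        ("2", (10.149, 9.950, 10.488), (-3.005, -2.854, -2.002), -2.620),
        ("3", (12.369, 9.327, 10.050), (-1.128, -4.196, -2.434), -2.586),
        ("4", (12.961, 9.592, 9.055), (-0.628, -3.626, -3.415), -2.557),
        ("5", (12.806, 9.849, 8.775), (-0.759, -3.072, -3.692), -2.508),
    ]
)
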