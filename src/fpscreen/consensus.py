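"""Consensus fingerprint similarity scoring.

The screening core: per-kind Euclidean distances from a query molecule to
every library member, z-score normalization of each kind's distance
distribution, a consensus score (the arithmetic mean of the normalized
scores across kinds), ranking, and an optional consensus cutoff filter.

For binary fingerprints the Euclidean distance is ``sqrt(h)`` where ``h``
is the Hamming count (number of differing bits), so every squared distance
is an integer — computed here as an exact set symmetric difference followed
by a single square root.

More negative consensus means more similar to the query: the library
distances of a close analog sit in the lower tail of every kind's
distribution, hence below the mean, hence with a negative z-score in every
kind.  Averaging across fingerprint families damps kind-specific artifacts:
a compound must look close under *all* requested representations to rank
highly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .chem_io import MoleculeRecord, round_half_away
from .fingerprints import BitFingerprint, FingerprintParams, LibraryIndex, fingerprint

logger = logging.getLogger("fpscreen.consensus")

__all__ = [
    "DegenerateDistributionError",
    "DistanceTable",
    "ScreenRow",
    "euclidean_distance",
    "zscore_normalize",
    "consensus_score",
    "apply_cutoff",
    "screen",
]


class DegenerateDistributionError(ValueError):
    """A distance distribution with zero variance cannot be z-normalized."""


def _check_comparable(a: BitFingerprint, b: BitFingerprint) -> None:
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind!r} vs {b.kind!r}")
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")


def euclidean_distance(a: BitFingerprint, b: BitFingerprint) -> float:
    """Euclidean distance between two binary fingerprints.

    Equals the square root of the symmetric-difference (Hamming) count;
    symmetric, and zero exactly when the bit sets are identical.
    """
    _check_comparable(a, b)
    return math.sqrt(len(a.on_bits ^ b.on_bits))


@dataclass(frozen=True)
class DistanceTable:
    """Raw query-to-library distances for one fingerprint kind."""

    kind: str
    values: np.ndarray  # aligned to library order, each >= 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


def zscore_normalize(values, *, ddof: int = 0) -> np.ndarray:
    """Center and scale a distance distribution to mean 0, sd 1.

    Uses the population standard deviation (``ddof=0``) by default.  A
    constant distribution cannot be scaled and raises
    :class:`DegenerateDistributionError`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("z-score normalization needs a 1-d array of length >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in distance distribution")
    sd = arr.std(ddof=ddof)
    if sd == 0.0:
        raise DegenerateDistributionError(
            "zero-variance distribution: all distances identical"
        )
    return (arr - arr.mean()) / sd


def consensus_score(norms) -> float:
    """Arithmetic mean of per-kind normalized scores; order-invariant."""
    arr = np.asarray(norms, dtype=float)
    if arr.size == 0:
        raise ValueError("consensus_score needs at least one normalized score")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite normalized score")
    return float(arr.mean())


@dataclass(frozen=True)
class ScreenRow:
    """One compound's screening result: raw and normalized per-kind scores.

    ``consensus`` always equals the arithmetic mean of ``norms.values()``
    (same kind order as ``kinds``).
    """

    compound_id: str
    kinds: tuple[str, ...]
    distances: dict[str, float]
    norms: dict[str, float]
    consensus: float

    def _table_spec(self):
        header = ["CompoundID"]
        for kind in self.kinds:
            header += [f"{kind}_dist", f"{kind}_norm"]
        header.append("consensus")

        def render(row: "ScreenRow") -> list[str]:
            cells = [row.compound_id]
            for kind in row.kinds:
                cells.append(round_half_away(row.distances[kind], 3))
                cells.append(round_half_away(row.norms[kind], 3))
            cells.append(round_half_away(row.consensus, 3))
            return cells

        return header, render


def apply_cutoff(rows: list[ScreenRow], cutoff: float) -> list[ScreenRow]:
    """Keep rows whose consensus is strictly below *cutoff*.

    The comparison is strict: a row sitting exactly on the cutoff is
    excluded.
    """
    return [r for r in rows if r.consensus < cutoff]


def screen(
    query: MoleculeRecord,
    index: LibraryIndex,
    cutoff: float | None = None,
    *,
    ddof: int = 0,
) -> list[ScreenRow]:
    """Rank a library by consensus similarity to *query*.

    Produces one row per library compound, sorted ascending by consensus
    (most negative = most similar) with ties broken by compound id; with a
    *cutoff*, only rows with consensus strictly below it are returned.

    The query is fingerprinted with the index's own parameters, so kind and
    length always match.  Any kind whose distance distribution has zero
    variance aborts the screen.
    """
    if query.smiles_canonical is None or not query.valid:
        raise ValueError("query must be a valid, standardized record")

    n = index.size
    distances: dict[str, np.ndarray] = {}
    norms: dict[str, np.ndarray] = {}
    for params in index.params:
        qfp = fingerprint(query, params)
        vals = np.array(
            [euclidean_distance(qfp, fp) for fp in index.fingerprints[params.kind]]
        )
        distances[params.kind] = vals
        try:
            norms[params.kind] = zscore_normalize(vals, ddof=ddof)
        except DegenerateDistributionError as exc:
            raise DegenerateDistributionError(
                f"kind {params.kind!r}: {exc}; cannot z-normalize this library"
            ) from exc
        logger.info(
            "kind %s: distance range [%.3f, %.3f] over %d compounds",
            params.kind, vals.min(), vals.max(), n,
        )

    kinds = index.kinds
    rows = [
        ScreenRow(
            compound_id=rec.id,
            kinds=kinds,
            distances={k: float(distances[k][i]) for k in kinds},
            norms={k: float(norms[k][i]) for k in kinds},
            consensus=consensus_score([norms[k][i] for k in kinds]),
        )
        for i, rec in enumerate(index.records)
    ]
    rows.sort(key=lambda r: (r.consensus, r.compound_id))
    if cutoff is not None:
        kept = apply_cutoff(rows, cutoff)
        logger.info(
            "screened %d compounds; %d pass consensus cutoff %s",
            n, len(kept), cutoff,
        )
        return kept
    logger.info("screened %d compounds (no cutoff)", n)
    return rows
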