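"""Hit-novelty analysis against a reference actives set.

After screening, each candidate hit is compared to a set of known actives
(e.g. a local export of compounds with reported activity on the target) by
Tanimoto similarity over Morgan radius-2 / 2048-bit (ECFP4) fingerprints.
The closest active, its similarity, and the comparison count are reported
per hit — a high similarity flags a likely rediscovery of a known compound
rather than a novel scaffold.

Actives pass through the same standardization pipeline as hits, so trivial
salt or charge variants of a known compound are detected as rediscoveries
(Tanimoto 1.0) rather than scored as distant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem_io import MoleculeRecord, standardize
from .fingerprints import BitFingerprint, FingerprintParams, fingerprint

logger = logging.getLogger("fpscreen.novelty")

__all__ = ["NoveltyRow", "tanimoto", "nearest_active", "novelty_table"]

DEFAULT_NOVELTY_PARAMS = FingerprintParams(kind="morgan_ecfp4")


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over the on-bit sets.

    Symmetric, in [0, 1]; equals 1 exactly for identical non-empty bit
    sets.  Two empty fingerprints share no evidence of similarity and score
    0 by convention.
    """
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind!r} vs {b.kind!r}")
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


@dataclass(frozen=True)
class NoveltyRow:
    """One hit's closest known active and the Tanimoto similarity to it."""

    hit_id: str
    closest_active_id: str
    tanimoto: float
    n_actives_compared: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto <= 1.0:
            raise ValueError("tanimoto must lie in [0, 1]")

    def _table_spec(self):
        header = ["hit_id", "closest_active_id", "tanimoto"]

        def render(row: "NoveltyRow") -> list[str]:
            from .chem_io import round_half_away

            return [row.hit_id, row.closest_active_id, round_half_away(row.tanimoto, 4)]

        return header, render


def _prepare(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    out = []
    for rec in records:
        if rec.smiles_canonical is None:
            rec = standardize(rec)
        if rec.valid:
            out.append(rec)
        else:
            logger.warning("dropping invalid active %s: %s", rec.id, rec.reason)
    return out


def nearest_active(
    hit: MoleculeRecord,
    actives: Sequence[MoleculeRecord],
    params: FingerprintParams = DEFAULT_NOVELTY_PARAMS,
) -> NoveltyRow:
    """Find the active with maximal Tanimoto similarity to *hit*.

    Ties are broken by active id (lexicographic), making the result
    independent of actives input order.
    """
    hit = standardize(hit) if hit.smiles_canonical is None else hit
    if not hit.valid:
        raise ValueError(f"hit {hit.id!r} is invalid: {hit.reason}")
    prepared = _prepare(actives)
    if not prepared:
        raise ValueError("actives set is empty or entirely invalid")
    hfp = fingerprint(hit, params)
    best_id: str | None = None
    best_sim = -1.0
    for active in prepared:
        sim = tanimoto(hfp, fingerprint(active, params))
        if sim > best_sim or (sim == best_sim and active.id < best_id):
            best_id, best_sim = active.id, sim
    return NoveltyRow(
        hit_id=hit.id,
        closest_active_id=best_id,
        tanimoto=best_sim,
        n_actives_compared=len(prepared),
    )


def novelty_table(
    hits: Sequence[MoleculeRecord],
    actives: Sequence[MoleculeRecord],
    params: FingerprintParams = DEFAULT_NOVELTY_PARAMS,
) -> list[NoveltyRow]:
    """Closest-active report for every hit, in hit order.

    Standardizes and fingerprints the actives once, then searches them for
    each hit; rows are identical to calling :func:`nearest_active` per hit.
    """
    prepared = _prepare(actives)
    if not prepared:
        raise ValueError("actives set is empty or entirely invalid")
    afps = [(a.id, fingerprint(a, params)) for a in prepared]
    rows = []
    for hit in hits:
        hit = standardize(hit) if hit.smiles_canonical is None else hit
        if not hit.valid:
            raise ValueError(f"hit {hit.id!r} is invalid: {hit.reason}")
        hfp = fingerprint(hit, params)
        best_id, best_sim = None, -1.0
        for aid, afp in afps:
            sim = tanimoto(hfp, afp)
            if sim > best_sim or (sim == best_sim and aid < best_id):
                best_id, best_sim = aid, sim
        rows.append(
            NoveltyRow(
                hit_id=hit.id,
                closest_active_id=best_id,
                tanimoto=best_sim,
                n_actives_compared=len(prepared),
            )
        )
    return rows
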