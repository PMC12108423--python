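"""Binary molecular fingerprints behind a pluggable backend registry.

Four bit-vector families are registered on top of RDKit:

``avalon``
    Path/feature-enumeration fingerprint from the Avalon toolkit (512 bits
    by default).
``ecfp``
    Extended-connectivity circular fingerprint of diameter 6 (Morgan radius
    3, 2048 bits by default).
``maccs_keys``
    The published 166-key MACCS substructure dictionary (167 bits, index 0
    unused by convention).
``morgan_ecfp4``
    Morgan radius-2 / 2048-bit fingerprint (ECFP4), the convention used for
    Tanimoto novelty analysis.

A fifth kind, ``pubchem_keys`` (the published 881-key PubChem substructure
screen), is registered as *unavailable* in this distribution: no installed
backend provides the full key dictionary.  Requesting it raises
:class:`UnavailableKindError`, which consensus screening downgrades to a
warning while continuing with the remaining kinds.

Correctness here is backend-agnostic by design: determinism, invariance to
input atom ordering, and metric behaviour of the emitted bit sets — not
bit-level parity with any particular external toolkit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem, rdBase
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem_io import MoleculeRecord

logger = logging.getLogger("fpscreen.fingerprints")

__all__ = [
    "BitFingerprint",
    "FingerprintParams",
    "LibraryIndex",
    "UnavailableKindError",
    "available_kinds",
    "registered_kinds",
    "fingerprint",
    "build_index",
    "FingerprintCache",
]

BACKEND_VERSION = f"rdkit-{rdBase.rdkitVersion}"


class UnavailableKindError(ValueError):
    """A registered fingerprint kind with no working backend."""


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary feature vector, stored sparsely.

    ``on_bits`` holds the sorted indices of set bits; all indices lie in
    ``[0, n_bits)``.  Two fingerprints are comparable only when both
    ``kind`` and ``n_bits`` match.
    """

    kind: str
    n_bits: int
    on_bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        object.__setattr__(self, "on_bits", frozenset(self.on_bits))
        if self.on_bits and not (
            0 <= min(self.on_bits) and max(self.on_bits) < self.n_bits
        ):
            raise ValueError("on_bits index outside [0, n_bits)")

    def to_hex(self) -> str:
        """Serialize as a big-endian hex bit-string (bit 0 = MSB of byte 0)."""
        n_bytes = (self.n_bits + 7) // 8
        buf = bytearray(n_bytes)
        for b in self.on_bits:
            buf[b // 8] |= 0x80 >> (b % 8)
        return bytes(buf).hex()

    @classmethod
    def from_hex(cls, kind: str, n_bits: int, hex_string: str) -> "BitFingerprint":
        buf = bytes.fromhex(hex_string)
        if len(buf) != (n_bits + 7) // 8:
            raise ValueError("hex string length does not match n_bits")
        on = frozenset(
            i for i in range(n_bits) if buf[i // 8] & (0x80 >> (i % 8))
        )
        return cls(kind=kind, n_bits=n_bits, on_bits=on)


_DEFAULT_BITS = {
    "avalon": 512,
    "ecfp": 2048,
    "pubchem_keys": 881,
    "morgan_ecfp4": 2048,
    "maccs_keys": 167,
}
_FIXED_RADIUS = {"ecfp": 3, "morgan_ecfp4": 2}


@dataclass(frozen=True)
class FingerprintParams:
    """Kind plus sizing parameters for one fingerprint family.

    ``radius`` applies to circular kinds only and is pinned by convention:
    ``ecfp`` means diameter 6 hence radius 3, ``morgan_ecfp4`` means radius
    2 (2048 bits by default).  ``maccs_keys`` has a fixed 167-bit length.
    """

    kind: str
    n_bits: int | None = None
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_BITS:
            raise ValueError(
                f"unknown fingerprint kind {self.kind!r}; registered kinds: "
                f"{sorted(_DEFAULT_BITS)}"
            )
        if self.n_bits is None:
            object.__setattr__(self, "n_bits", _DEFAULT_BITS[self.kind])
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if self.kind == "maccs_keys" and self.n_bits != 167:
            raise ValueError("maccs_keys is a fixed 167-bit dictionary")
        fixed = _FIXED_RADIUS.get(self.kind)
        if fixed is not None:
            if self.radius is None:
                object.__setattr__(self, "radius", fixed)
            elif self.radius != fixed:
                raise ValueError(
                    f"kind {self.kind!r} implies radius {fixed}, got {self.radius}"
                )
        elif self.radius is not None:
            raise ValueError(f"kind {self.kind!r} takes no radius parameter")


def _avalon_bits(mol: Chem.Mol, params: FingerprintParams) -> frozenset[int]:
    bv = pyAvalonTools.GetAvalonFP(mol, nBits=params.n_bits)
    return frozenset(bv.GetOnBits())


def _morgan_bits(mol: Chem.Mol, params: FingerprintParams) -> frozenset[int]:
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=params.radius, fpSize=params.n_bits
    )
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def _maccs_bits(mol: Chem.Mol, params: FingerprintParams) -> frozenset[int]:
    return frozenset(MACCSkeys.GenMACCSKeys(mol).GetOnBits())


def _pubchem_unavailable(mol: Chem.Mol, params: FingerprintParams) -> frozenset[int]:
    raise UnavailableKindError(
        "pubchem_keys: no backend providing the published 881-key dictionary "
        f"is installed; available kinds: {sorted(available_kinds())}"
    )


_BACKENDS: dict[str, Callable[[Chem.Mol, FingerprintParams], frozenset[int]]] = {
    "avalon": _avalon_bits,
    "ecfp": _morgan_bits,
    "morgan_ecfp4": _morgan_bits,
    "maccs_keys": _maccs_bits,
    "pubchem_keys": _pubchem_unavailable,
}
_UNAVAILABLE = {"pubchem_keys"}


def registered_kinds() -> set[str]:
    """All kind names the registry knows, available or not."""
    return set(_BACKENDS)


def available_kinds() -> set[str]:
    """Kind names with a working backend."""
    return set(_BACKENDS) - _UNAVAILABLE


def fingerprint(record: MoleculeRecord, params: FingerprintParams) -> BitFingerprint:
    """Fingerprint a valid, standardized record.

    Deterministic: the same canonical SMILES and params always yield the
    identical bit set, across processes (no hash-seed dependence).
    """
    if not record.valid:
        raise ValueError(f"cannot fingerprint invalid record {record.id!r}: {record.reason}")
    if record.smiles_canonical is None:
        raise ValueError(f"record {record.id!r} is not standardized")
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:  # canonical SMILES should always re-parse
        raise ValueError(f"canonical SMILES of {record.id!r} does not re-parse")
    on_bits = _BACKENDS[params.kind](mol, params)
    return BitFingerprint(kind=params.kind, n_bits=params.n_bits, on_bits=on_bits)


@dataclass(frozen=True)
class LibraryIndex:
    """Aligned per-kind fingerprint arrays over one molecule collection.

    ``fingerprints[kind][i]`` belongs to ``records[i]``; alignment between
    kinds is by position and id.  Records that were invalid or failed
    fingerprinting for *any* kind are excluded from all kinds (ids listed
    in ``excluded``).
    """

    records: tuple[MoleculeRecord, ...]
    params: tuple[FingerprintParams, ...]
    fingerprints: dict[str, tuple[BitFingerprint, ...]]
    excluded: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.records)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(p.kind for p in self.params)

    def params_for(self, kind: str) -> FingerprintParams:
        for p in self.params:
            if p.kind == kind:
                return p
        raise KeyError(kind)


def build_index(
    records: Iterable[MoleculeRecord],
    params_list: Sequence[FingerprintParams],
) -> LibraryIndex:
    """Fingerprint a library with every params entry into a LibraryIndex.

    Requires at least two indexable records: downstream z-score
    normalization needs a non-degenerate distance distribution.  Unavailable
    kinds are dropped with a warning; an error is raised only when no
    requested kind has a backend.
    """
    params_list = list(params_list)
    if not params_list:
        raise ValueError("at least one FingerprintParams entry is required")
    seen_kinds = [p.kind for p in params_list]
    if len(set(seen_kinds)) != len(seen_kinds):
        raise ValueError(f"duplicate kinds in params list: {seen_kinds}")

    usable = [p for p in params_list if p.kind not in _UNAVAILABLE]
    for p in params_list:
        if p.kind in _UNAVAILABLE:
            logger.warning(
                "fingerprint kind %r has no available backend; "
                "continuing with %s", p.kind, [q.kind for q in usable],
            )
    if not usable:
        raise UnavailableKindError(
            f"none of the requested kinds {seen_kinds} has an available "
            f"backend; available kinds: {sorted(available_kinds())}"
        )

    kept: list[MoleculeRecord] = []
    per_kind: dict[str, list[BitFingerprint]] = {p.kind: [] for p in usable}
    excluded: list[str] = []
    for rec in records:
        if not rec.valid:
            excluded.append(rec.id)
            logger.info("excluding %s: %s", rec.id, rec.reason)
            continue
        fps: dict[str, BitFingerprint] = {}
        try:
            for p in usable:
                fps[p.kind] = fingerprint(rec, p)
        except (ValueError, RuntimeError) as exc:
            excluded.append(rec.id)
            logger.warning("excluding %s from all kinds: %s", rec.id, exc)
            continue
        kept.append(rec)
        for kind, fp in fps.items():
            per_kind[kind].append(fp)

    if len(kept) < 2:
        raise ValueError(
            f"library index needs >= 2 valid records (got {len(kept)}): "
            "z-score normalization requires a non-degenerate distance "
            "distribution"
        )
    if excluded:
        logger.info("excluded %d of %d records", len(excluded), len(excluded) + len(kept))
    return LibraryIndex(
        records=tuple(kept),
        params=tuple(usable),
        fingerprints={k: tuple(v) for k, v in per_kind.items()},
        excluded=tuple(excluded),
    )


class FingerprintCache:
    """Optional on-disk fingerprint cache, keyed by structure and params.

    One JSON object per file, mapping
    ``"<canonical SMILES>|<kind>|<n_bits>|<backend version>"`` to the hex
    serialization of the bit set.  Purely an optimization; results are
    identical with or without it.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._data: dict[str, str] = {}
        if self.path.exists():
            self._data = json.loads(self.path.read_text())

    @staticmethod
    def _key(smiles: str, params: FingerprintParams) -> str:
        return f"{smiles}|{params.kind}|{params.n_bits}|{BACKEND_VERSION}"

    def get(self, record: MoleculeRecord, params: FingerprintParams) -> BitFingerprint:
        key = self._key(record.smiles_canonical or "", params)
        if key in self._data:
            return BitFingerprint.from_hex(params.kind, params.n_bits, self._data[key])
        fp = fingerprint(record, params)
        self._data[key] = fp.to_hex()
        return fp

    def save(self) -> None:
        self.path.write_text(json.dumps(self._data))
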