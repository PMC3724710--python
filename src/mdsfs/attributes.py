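"""Physicochemical amino-acid attribute tables and sequence encoding.

An *attribute* maps each of the 20 standard amino acids to a real number
(hydrophobicity, polarity, volume, ...).  The bundled default table holds the
30 attributes used throughout the package, each identified by a single
case-sensitive symbol ('H' = hydrophobicity, 'P' = polarity, ..., 'F' =
normalized beta-sheet frequency, 'f' = frequency of the first residue in a
turn).  Attribute subsets are written as concatenated symbols, e.g. "HPZXV".

Residue letters are matched case-insensitively; attribute symbols are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    DuplicateSymbolError,
    TableFormatError,
    UnknownSymbolError,
)

logger = logging.getLogger(__name__)

#: Residue column order used by attribute table files (one-letter, lowercase).
RESIDUE_ORDER: tuple[str, ...] = tuple("acdefghiklmnpqrstvwy")

_RESIDUE_SET = frozenset(RESIDUE_ORDER)


@dataclass(frozen=True)
class PhysicochemicalAttribute:
    """One per-residue numeric property of the 20 standard amino acids.

    Parameters
    ----------
    symbol : str
        Single case-sensitive identifying character.
    name : str
        Human-readable property name.
    index : int
        1-based position in the owning table.
    values : mapping
        Residue (lowercase one-letter) -> value; exactly the 20 standard
        residues, all finite.
    """

    symbol: str
    name: str
    index: int
    values: Mapping[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if not self.symbol:
            raise TableFormatError("attribute symbol must be nonempty")
        keys = set(self.values)
        if keys != _RESIDUE_SET:
            missing = sorted(_RESIDUE_SET - keys)
            extra = sorted(keys - _RESIDUE_SET)
            raise TableFormatError(
                f"attribute {self.symbol!r}: residue keys mismatch "
                f"(missing {missing}, unexpected {extra})"
            )
        if not all(np.isfinite(list(self.values.values()))):
            raise TableFormatError(f"attribute {self.symbol!r}: non-finite value")

    def value(self, residue: str) -> float:
        """Value for one residue letter (case-insensitive)."""
        return self.values[residue.lower()]

    def value_array(self) -> np.ndarray:
        """Values in :data:`RESIDUE_ORDER`, as a length-20 float array."""
        return np.array([self.values[r] for r in RESIDUE_ORDER], dtype=float)


class AttributeTable:
    """Ordered collection of :class:`PhysicochemicalAttribute` with symbol lookup."""

    def __init__(self, attributes: Iterable[PhysicochemicalAttribute]):
        self._attributes: tuple[PhysicochemicalAttribute, ...] = tuple(attributes)
        self._by_symbol: dict[str, PhysicochemicalAttribute] = {}
        for attr in self._attributes:
            if attr.symbol in self._by_symbol:
                raise DuplicateSymbolError(
                    f"duplicate attribute symbol {attr.symbol!r}"
                )
            self._by_symbol[attr.symbol] = attr

    def __len__(self) -> int:
        return len(self._attributes)

    def __iter__(self):
        return iter(self._attributes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, key: str | int) -> PhysicochemicalAttribute:
        """Look up by case-sensitive symbol (str) or 1-based index (int)."""
        if isinstance(key, str):
            try:
                return self._by_symbol[key]
            except KeyError:
                raise UnknownSymbolError(key) from None
        return self._attributes[key - 1]

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(a.symbol for a in self._attributes)

    def to_frame(self):
        """Table as a pandas DataFrame (symbol, name, residue columns)."""
        import pandas as pd

        rows = [
            {"symbol": a.symbol, "name": a.name,
             **{r: a.values[r] for r in RESIDUE_ORDER}}
            for a in self._attributes
        ]
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        """Write the table in the TSV interchange layout read by :func:`load_table`."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@lru_cache(maxsize=1)
def load_default_table() -> AttributeTable:
    """Load the bundled 30-attribute table.

    Returns the same cached instance on repeated calls.
    """
    ref = resources.files("mdsfs").joinpath("data/attribute_table.tsv")
    with resources.as_file(ref) as path:
        table = load_table(path)
    if len(table) != 30:
        raise TableFormatError(
            f"packaged attribute table is corrupt: {len(table)} entries, expected 30"
        )
    return table


def load_table(path: str | Path) -> AttributeTable:
    """Parse an attribute table from a TSV file.

    Expected layout: a header row ``symbol name a c d e f g h i k l m n p q
    r s t v w y`` followed by one row per attribute.
    """
    import pandas as pd

    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "name": str})
    except Exception as exc:  # noqa: BLE001 - rewrap any parse failure
        raise TableFormatError(f"cannot parse attribute table {path}: {exc}") from exc

    required = ["symbol", "name", *RESIDUE_ORDER]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"'symbol name {' '.join(RESIDUE_ORDER)}'"
        )

    attributes = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = row._asdict()
        values = {}
        for r in RESIDUE_ORDER:
            v = rowd[r]
            try:
                values[r] = float(v)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}: row {i} (symbol {rowd['symbol']!r}): "
                    f"non-numeric value {v!r} for residue {r!r}"
                ) from None
        try:
            attributes.append(
                PhysicochemicalAttribute(
                    symbol=str(rowd["symbol"]), name=str(rowd["name"]),
                    index=i, values=values,
                )
            )
        except TableFormatError as exc:
            raise TableFormatError(f"{path}: row {i}: {exc}") from exc
    try:
        return AttributeTable(attributes)
    except DuplicateSymbolError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


def encode_sequence(
    seq: str, attr: PhysicochemicalAttribute, *, warn: bool = True
) -> np.ndarray:
    """Map an amino-acid sequence to the attribute's per-residue value series.

    Residue letters are matched case-insensitively.  Characters outside the
    20 standard residues (B, J, O, U, X, Z, gaps, ...) are skipped with a
    logged warning rather than imputed: attribute values are defined only for
    the standard residues.

    Raises
    ------
    DegenerateInputError
        If the sequence is empty or no residue is recognized.
    """
    lowered = seq.lower()
    recognized = [c for c in lowered if c in _RESIDUE_SET]
    if not recognized:
        raise DegenerateInputError(
            "sequence is empty or contains no recognized standard residue"
        )
    if warn and len(recognized) < len(lowered):
        skipped = sorted({c for c in lowered if c not in _RESIDUE_SET})
        logger.warning(
            "skipped %d unrecognized residue character(s) %s",
            len(lowered) - len(recognized), skipped,
        )
    return np.array([attr.values[c] for c in recognized], dtype=float)


def parse_subset(
    symbols: str, table: AttributeTable | None = None
) -> tuple[PhysicochemicalAttribute, ...]:
    """Parse a concatenated-symbol subset string (e.g. ``"HPZXV"``).

    Symbols are case-sensitive and may not repeat; order is preserved.
    """
    if table is None:
        table = load_default_table()
    seen: set[str] = set()
    out = []
    for ch in symbols:
        if ch in seen:
            raise DuplicateSymbolError(f"repeated symbol {ch!r} in subset {symbols!r}")
        if ch not in table:
            raise UnknownSymbolError(f"unknown attribute symbol {ch!r} in {symbols!r}")
        seen.add(ch)
        out.append(table[ch])
    return tuple(out)


def render_subset(attrs: Sequence[PhysicochemicalAttribute]) -> str:
    """Inverse of :func:`parse_subset`: concatenate subset symbols in order."""
    return "".join(a.symbol for a in attrs)
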