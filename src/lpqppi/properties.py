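"""Amino-acid property tables.

A :class:`PropertyTable` maps each of the 20 canonical one-letter residue
codes to a real scalar (e.g. a hydrophobicity index).  The packaged default
is the hydrophobicity scale used throughout this package; it ships as a
two-column TSV under ``lpqppi/data`` and additional scales can be loaded
from files of the same format.

Non-canonical letters are resolved by an *ambiguity policy*:

``mean``
    B -> mean(N, D), Z -> mean(Q, E), J -> mean(I, L); any other unknown
    letter (X, U, O, ...) -> mean of all 20 canonical values.
``strict``
    any non-canonical letter is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "CANONICAL_RESIDUES",
    "PropertyTable",
    "UnknownResidueError",
    "load_property_table",
    "hydrophobicity_table",
    "lookup_property",
]

CANONICAL_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: two-letter expansions for the standard ambiguity codes
_AMBIGUOUS_PAIRS = {"B": "ND", "Z": "QE", "J": "IL"}

_POLICIES = ("mean", "strict")


class UnknownResidueError(ValueError):
    """Raised for a residue letter the active policy cannot resolve."""

    def __init__(self, residue: str, position: int | None = None):
        self.residue = residue
        self.position = position
        where = "" if position is None else f" at position {position}"
        super().__init__(f"unknown residue {residue!r}{where}")


@dataclass(frozen=True)
class PropertyTable:
    """A per-residue scalar property scale.

    Parameters
    ----------
    property_id
        Short label for the scale (e.g. ``"hydrophobicity"``).
    values
        Mapping from each of the 20 canonical residues to a finite real.
    ambiguous_policy
        ``"mean"`` (default) or ``"strict"``; see module docstring.
    """

    property_id: str
    values: Mapping[str, float]
    ambiguous_policy: str = "mean"

    def __post_init__(self) -> None:
        if self.ambiguous_policy not in _POLICIES:
            raise ValueError(
                f"ambiguous_policy must be one of {_POLICIES}, "
                f"got {self.ambiguous_policy!r}"
            )
        keys = set(self.values)
        expected = set(CANONICAL_RESIDUES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"property table must cover exactly the 20 canonical residues; "
                f"missing={missing}, unexpected={extra}"
            )
        for res, val in self.values.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite value {val!r} for residue {res!r}")
        # freeze the mapping so the table is safely hashable by identity
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)

    def lookup(self, residue: str, position: int | None = None) -> float:
        """Value for ``residue``; ambiguity handled per policy.

        ``position`` (0-based) only decorates the error message.
        """
        res = residue.upper()
        if len(res) != 1 or not res.isalpha():
            raise UnknownResidueError(residue, position)
        try:
            return self.values[res]
        except KeyError:
            pass
        if self.ambiguous_policy == "strict":
            raise UnknownResidueError(res, position)
        pair = _AMBIGUOUS_PAIRS.get(res)
        if pair is not None:
            return (self.values[pair[0]] + self.values[pair[1]]) / 2.0
        return self.mean

    def vectorize(self, sequence: str) -> list[float]:
        """Per-position property values for an upper-cased sequence."""
        return [self.lookup(res, pos) for pos, res in enumerate(sequence)]


def lookup_property(table: PropertyTable, residue: str) -> float:
    """Functional alias for :meth:`PropertyTable.lookup`."""
    return table.lookup(residue)


def load_property_table(
    path: str | Path,
    property_id: str | None = None,
    ambiguous_policy: str = "mean",
) -> PropertyTable:
    """Load a scale from a two-column TSV (residue, value).

    A single header line is allowed and detected by a non-numeric second
    column.
    """
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            res, raw = parts
            try:
                val = float(raw)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric value {raw!r}") from None
            res = res.strip().upper()
            if res in values:
                raise ValueError(f"{path}:{lineno}: duplicate residue {res!r}")
            values[res] = val
    return PropertyTable(
        property_id=property_id or path.stem,
        values=values,
        ambiguous_policy=ambiguous_policy,
    )


def hydrophobicity_table(ambiguous_policy: str = "mean") -> PropertyTable:
    """The packaged per-residue hydrophobicity scale (the default property)."""
    ref = resources.files("lpqppi.data") / "hydrophobicity.tsv"
    with resources.as_file(ref) as path:
        return load_property_table(
            path, property_id="hydrophobicity", ambiguous_policy=ambiguous_policy
        )
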