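"""Canonical amino-acid alphabet and biochemical residue grouping.

Every module in the package indexes residues through the fixed 21-letter
alphabet defined here: the 20 standard amino acids in alphabetical order
followed by ``X``, the terminal-padding / unknown-residue symbol. Keeping a
single canonical ordering makes feature-vector columns and contingency-table
axes stable across runs and serialisations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

#: The 20 standard amino acids, alphabetically by one-letter code.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: Padding / unknown symbol.
PAD: str = "X"

#: Full 21-letter alphabet (AA20 then X), the canonical column order.
ALPHABET: str = AA20 + PAD

#: Letter -> 0..20 index into :data:`ALPHABET`.
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: Ambiguity / non-standard codes collapsed to X on read.
NONSTANDARD: frozenset[str] = frozenset("BZUOJ")

_NONSTANDARD_TABLE = str.maketrans({c: PAD for c in NONSTANDARD})


def sanitize_sequence(seq: str) -> str:
    """Uppercase *seq* and map non-standard letters (B, Z, U, O, J) to X.

    Raises
    ------
    ValueError
        If a character outside the 21-letter alphabet remains afterwards.
    """
    clean = seq.upper().translate(_NONSTANDARD_TABLE)
    bad = set(clean) - set(ALPHABET)
    if bad:
        raise ValueError(f"sequence contains non amino-acid letters: {sorted(bad)}")
    return clean


@dataclass(frozen=True)
class ResidueGroupScheme:
    """Partition of the 20 standard amino acids into biochemical groups.

    The default five-way partition (polar / acidic / basic / hydrophobic /
    aromatic) drives the grouped chi-square statistic used by maximal
    dependence decomposition. ``X`` belongs to no group.

    Parameters
    ----------
    groups
        Ordered group names; the order fixes group indices and tie-breaks.
    membership
        One-letter residue code -> group name, covering exactly the 20
        standard amino acids.
    """

    groups: tuple[str, ...]
    membership: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.membership) != set(AA20):
            missing = set(AA20) - set(self.membership)
            extra = set(self.membership) - set(AA20)
            raise ValueError(
                f"membership must cover the 20 standard residues exactly "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        bad = set(self.membership.values()) - set(self.groups)
        if bad:
            raise ValueError(f"membership references unknown groups: {sorted(bad)}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, residue: str) -> str | None:
        """Group name for *residue*, or None for X."""
        return self.membership.get(residue)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, g in self.membership.items() if g == group))

    def codes(self) -> "dict[str, int]":
        """Residue letter -> group index; X is absent."""
        return {a: self.groups.index(g) for a, g in self.membership.items()}

    def to_json(self) -> str:
        return json.dumps({"groups": list(self.groups), "membership": dict(self.membership)})

    @classmethod
    def from_json(cls, text: str) -> "ResidueGroupScheme":
        obj = json.loads(text)
        return cls(groups=tuple(obj["groups"]), membership=dict(obj["membership"]))

    @classmethod
    def from_file(cls, path: str | Path) -> "ResidueGroupScheme":
        return cls.from_json(Path(path).read_text())


def _default_membership() -> dict[str, str]:
    blocks = {
        "polar": "STNQCG",
        "acidic": "DE",
        "basic": "KRH",
        "hydrophobic": "AVLIMP",
        "aromatic": "FWY",
    }
    return {a: g for g, aas in blocks.items() for a in aas}


#: Default biochemical grouping. Basic = {K, R, H} is the one membership the
#: field fixes unambiguously; the remaining assignments are conventional and
#: replaceable via a scheme file.
DEFAULT_SCHEME = ResidueGroupScheme(
    groups=("polar", "acidic", "basic", "hydrophobic", "aromatic"),
    membership=_default_membership(),
)
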