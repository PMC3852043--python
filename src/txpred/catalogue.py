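"""Feature catalogue: the ordered inventory of named transcript features.

Each feature carries the transcript segment it is computed from
(``segment_scope``), which drives the segment-restricted predictors: a
5'UTR-only predictor may draw only on UTR5-scoped features, while the
whole-transcript scope admits every feature.  Features whose computation
requires expression measurements (the mRNA-optimized adaptation indices of
scheme B) are flagged so the leakage guard can keep them out of scheme A.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

SCOPES = ("UTR5", "ORF", "UTR3", "TRANSCRIPT")
FAMILIES = (
    "length", "composition", "codon", "aa", "codon_pair", "aa_pair",
    "init", "adaptation", "folding", "pars", "tasep",
)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    segment_scope: str
    family: str
    default_value: float = 0.0
    requires_expression: bool = False

    def __post_init__(self) -> None:
        if self.segment_scope not in SCOPES:
            raise ValueError(f"unknown scope {self.segment_scope!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


class FeatureCatalogue:
    """Ordered, name-unique collection of :class:`FeatureDef`."""

    def __init__(self, defs: Iterable[FeatureDef] = ()) -> None:
        self._defs: dict[str, FeatureDef] = {}
        for d in defs:
            self.add(d)

    def add(self, d: FeatureDef) -> None:
        if d.name in self._defs:
            raise ValueError(f"duplicate feature name {d.name!r}")
        self._defs[d.name] = d

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self) -> Iterator[FeatureDef]:
        return iter(self._defs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __getitem__(self, name: str) -> FeatureDef:
        return self._defs[name]

    @property
    def names(self) -> list[str]:
        return list(self._defs)

    def scope_names(self, scope: str) -> list[str]:
        """Candidate features for a segment-restricted predictor.

        ``TRANSCRIPT`` means the combined predictor and admits everything.
        """
        if scope == "TRANSCRIPT":
            return self.names
        if scope not in SCOPES:
            raise ValueError(f"unknown scope {scope!r}")
        return [d.name for d in self if d.segment_scope == scope]

    def defaults(self) -> dict[str, float]:
        return {d.name: d.default_value for d in self}

    def subset(self, names: Iterable[str]) -> "FeatureCatalogue":
        return FeatureCatalogue(self._defs[n] for n in names)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tsegment_scope\tfamily\tdefault_value\trequires_expression\n")
            for d in self:
                fh.write(
                    f"{d.name}\t{d.segment_scope}\t{d.family}\t"
                    f"{d.default_value:g}\t{int(d.requires_expression)}\n"
                )
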