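"""Sample design for the 2x2 crossed parental x offspring treatment layout.

Each sample belongs to one of four groups coded by two letters: the first
letter is the parental-generation treatment, the second the offspring
(direct) treatment, with C = control and J = jasmonic acid. The default
layout has six replicate plants per group except CJ, which has five
(one library was dropped during quality control in the emulated study).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUPS: tuple[str, ...] = ("CC", "CJ", "JC", "JJ")
TREATMENTS: tuple[str, str] = ("C", "J")

#: replicate counts per group in the post-exclusion design
DEFAULT_GROUP_SIZES: dict[str, int] = {"CC": 6, "CJ": 5, "JC": 6, "JJ": 6}


@dataclass(frozen=True)
class Design:
    """Assignment of samples to the four experimental groups.

    Wraps a DataFrame indexed by ``sample_id`` with columns ``parental``,
    ``offspring``, ``group`` and ``replicate_index``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"parental", "offspring", "group", "replicate_index"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        bad = t[t["group"] != t["parental"] + t["offspring"]]
        if len(bad):
            raise ValueError(f"group label inconsistent with treatments for {list(bad.index)}")
        unknown = set(t["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        for g in GROUPS:
            if (t["group"] == g).sum() == 0:
                raise ValueError(f"group {g} is empty")

    @classmethod
    def default(cls, sizes: dict[str, int] | None = None) -> "Design":
        """The study layout: n = 6 per group, 5 in CJ."""
        sizes = dict(DEFAULT_GROUP_SIZES if sizes is None else sizes)
        rows = []
        for g in GROUPS:
            for i in range(1, sizes[g] + 1):
                rows.append(
                    {
                        "sample_id": f"{g}{i}",
                        "parental": g[0],
                        "offspring": g[1],
                        "group": g,
                        "replicate_index": i,
                    }
                )
        return cls(pd.DataFrame(rows).set_index("sample_id"))

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.table["group"] == g).sum()) for g in GROUPS}

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.table.index[self.table["group"] == group])

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    @property
    def group_labels(self) -> pd.Series:
        """Series sample_id -> group."""
        return self.table["group"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "Design":
        t = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"replicate_index": int})
        return cls(t)
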