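"""Experimental design, leaf-sample enumeration and pair classification.

A field trial is organised as families × blocks, with at most one plot per
(family, block) cell and a single clone per plot.  Three classes of leaf-sample
pairs arise:

* ``C1`` — same family and same block: both leaves come from the same plot,
  hence the same individual (clone).
* ``C2`` — same family, different blocks: different individuals of the same
  full-sib family.
* ``C3`` — different families: different individuals, unrelated plots.

These classes are the ground truth against which both dissimilarity stages are
evaluated.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DesignError",
    "ExperimentalDesign",
    "LeafSample",
    "PairClass",
    "PairRecord",
    "enumerate_samples",
    "classify_pair",
    "enumerate_pairs",
    "families_in_all_blocks",
    "filter_samples_to_families",
    "pairs_to_dataframe",
    "write_pairs_csv",
    "step2_design",
    "study_design",
]


class DesignError(ValueError):
    """Raised when an experimental design or a pair request is invalid."""


class PairClass(str, enum.Enum):
    """Table of pair classes: same plot, same family, or different family."""

    C1 = "C1"
    C2 = "C2"
    C3 = "C3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ExperimentalDesign:
    """Families × blocks layout with per-cell plot presence.

    Parameters
    ----------
    families, blocks:
        Ordered identifiers.  Order fixes the deterministic sample ordering.
    presence:
        Set of (family, block) cells that actually contain a plot.
    leaves_per_plot:
        Number of "+1" leaves collected per plot (study value: 3).
    """

    families: tuple[str, ...]
    blocks: tuple[str, ...]
    presence: frozenset[tuple[str, str]]
    leaves_per_plot: int = 3

    def __post_init__(self) -> None:
        if self.leaves_per_plot < 1:
            raise DesignError("leaves_per_plot must be >= 1")
        if len(set(self.families)) != len(self.families):
            raise DesignError("duplicate family identifiers")
        if len(set(self.blocks)) != len(self.blocks):
            raise DesignError("duplicate block identifiers")
        fams = set(self.families)
        blks = set(self.blocks)
        for fam, blk in self.presence:
            if fam not in fams:
                raise DesignError(f"presence references unknown family {fam!r}")
            if blk not in blks:
                raise DesignError(f"presence references unknown block {blk!r}")
        present_fams = {fam for fam, _ in self.presence}
        missing = fams - present_fams
        if missing:
            raise DesignError(
                f"families with no plot in any block: {sorted(missing)}"
            )

    @classmethod
    def from_mapping(
        cls,
        families: Sequence[str],
        blocks: Sequence[str],
        presence: Iterable[tuple[str, str]] | Mapping[tuple[str, str], bool] | None = None,
        leaves_per_plot: int = 3,
    ) -> "ExperimentalDesign":
        """Build a design; ``presence=None`` means every cell has a plot."""
        if presence is None:
            cells = frozenset(itertools.product(families, blocks))
        elif isinstance(presence, Mapping):
            cells = frozenset(k for k, v in presence.items() if v)
        else:
            cells = frozenset(tuple(p) for p in presence)
        return cls(tuple(families), tuple(blocks), cells, leaves_per_plot)

    def plots(self) -> list[tuple[str, str]]:
        """Present (family, block) cells in deterministic design order."""
        return [
            (fam, blk)
            for fam in self.families
            for blk in self.blocks
            if (fam, blk) in self.presence
        ]

    def n_samples(self) -> int:
        return len(self.plots()) * self.leaves_per_plot

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "families": list(self.families),
            "blocks": list(self.blocks),
            "presence": sorted([list(p) for p in self.presence]),
            "leaves_per_plot": self.leaves_per_plot,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentalDesign":
        try:
            return cls.from_mapping(
                d["families"],
                d["blocks"],
                [tuple(p) for p in d["presence"]] if d.get("presence") else None,
                int(d.get("leaves_per_plot", 3)),
            )
        except KeyError as exc:  # missing required key
            raise DesignError(f"design file missing key {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentalDesign":
        """Load from YAML or JSON (decided by suffix, YAML by default)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True, order=True)
class LeafSample:
    """One "+1" leaf with its plot identity."""

    sample_id: str
    family: str = field(compare=False)
    block: str = field(compare=False)
    leaf_index: int = field(compare=False)


@dataclass(frozen=True)
class PairRecord:
    """An unordered pair of leaf samples with its class.

    Canonicalised so that ``sample_a.sample_id < sample_b.sample_id``.
    """

    sample_a: LeafSample
    sample_b: LeafSample
    pair_class: PairClass

    def __post_init__(self) -> None:
        if self.sample_a.sample_id >= self.sample_b.sample_id:
            raise DesignError("pair not in canonical order (a.id < b.id)")


def default_sample_id(family: str, block: str, leaf_index: int) -> str:
    return f"{family}_{block}_{leaf_index}"


def enumerate_samples(design: ExperimentalDesign) -> list[LeafSample]:
    """All leaf samples of a design, ordered by (family, block, leaf_index)."""
    return [
        LeafSample(default_sample_id(fam, blk, leaf), fam, blk, leaf)
        for fam, blk in design.plots()
        for leaf in range(1, design.leaves_per_plot + 1)
    ]


def classify_pair(a: LeafSample, b: LeafSample) -> PairClass:
    """Class of an unordered pair; symmetric in its arguments."""
    if a.sample_id == b.sample_id:
        raise DesignError("cannot classify a sample against itself")
    if a.family != b.family:
        return PairClass.C3
    if a.block == b.block:
        return PairClass.C1
    return PairClass.C2


def enumerate_pairs(samples: Sequence[LeafSample]) -> list[PairRecord]:
    """All C(n, 2) unordered pairs, each classified.

    Pairs are canonicalised by lexicographic sample_id, so the output is
    independent of the input order up to reordering.
    """
    if len(samples) < 2:
        raise DesignError("need at least two samples to form pairs")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate sample ids: {dupes}")
    ordered = sorted(samples, key=lambda s: s.sample_id)
    return [
        PairRecord(a, b, classify_pair(a, b))
        for a, b in itertools.combinations(ordered, 2)
    ]


def families_in_all_blocks(design: ExperimentalDesign) -> list[str]:
    """Families with a plot in every block (the dual-block analysis subset)."""
    return [
        fam
        for fam in design.families
        if all((fam, blk) in design.presence for blk in design.blocks)
    ]


def filter_samples_to_families(
    samples: Iterable[LeafSample], families: Iterable[str]
) -> list[LeafSample]:
    keep = set(families)
    return [s for s in samples if s.family in keep]


def pairs_to_dataframe(pairs: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_a": [p.sample_a.sample_id for p in pairs],
            "sample_b": [p.sample_b.sample_id for p in pairs],
            "pair_class": [p.pair_class.value for p in pairs],
        }
    )


def write_pairs_csv(pairs: Sequence[PairRecord], path: str | Path) -> None:
    pairs_to_dataframe(pairs).to_csv(path, index=False)


def step2_design(
    n_families: int = 7, n_blocks: int = 2, leaves_per_plot: int = 3
) -> ExperimentalDesign:
    """The dual-block analysis subset: families present in every block.

    Defaults give 7 families × 2 blocks × 3 leaves = 42 samples and hence
    C(42, 2) = 861 pairs (42 C1, 63 C2, 756 C3).
    """
    families = [f"F{i:02d}" for i in range(1, n_families + 1)]
    blocks = [f"B{j}" for j in range(1, n_blocks + 1)]
    return ExperimentalDesign.from_mapping(families, blocks, None, leaves_per_plot)


def study_design(
    n_dual: int = 7,
    n_block1_only: int = 7,
    n_block2_only: int = 17,
    leaves_per_plot: int = 3,
) -> ExperimentalDesign:
    """The full two-block study layout.

    31 families in total: ``n_dual`` present in both blocks, the rest in one
    block only, giving 14 plots in block 1 and 24 in block 2 at the defaults.
    Which block-1 clones overlap block 2 is an explicit choice here (the first
    ``n_dual`` family labels), not something inferable from the field layout.
    """
    n_fam = n_dual + n_block1_only + n_block2_only
    families = [f"F{i:02d}" for i in range(1, n_fam + 1)]
    blocks = ["B1", "B2"]
    presence: list[tuple[str, str]] = []
    for i, fam in enumerate(families):
        if i < n_dual:
            presence += [(fam, "B1"), (fam, "B2")]
        elif i < n_dual + n_block1_only:
            presence.append((fam, "B1"))
        else:
            presence.append((fam, "B2"))
    return ExperimentalDesign.from_mapping(families, blocks, presence, leaves_per_plot)
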