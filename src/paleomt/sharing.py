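"""Shared-haplotype analysis (SHA) and ancestral SHA.

Two individuals share a *lineage* when their window-clipped HVS-I variant
sets are identical; reference-identical (and otherwise uninformative)
haplotypes are additionally split by their basal haplogroup (the first
letter-level clade: H vs. V vs. HV vs. U ...), since an rCRS-like HVS-I
sequence is compatible with several clades and the coding-region call is
what separates them.

The plain SHA matrix entry M[X][Y] is the percentage of the *column* group
Y's individuals whose lineage occurs anywhere in the row group X; the
diagonal is 100 by construction and every entry is an integer multiple of
100/n_Y.  The ancestral SHA credits each individual of a group to the
*earliest* (lowest-rank) group whose lineage set contains their lineage;
lineages absent from all earlier groups are "new", so each row sums to 100
and the oldest group is 100% new.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import Dataset, GroupDefinition, Individual
from .haplogroup_typing import FALLBACK_LABEL, MotifTree


@dataclass(frozen=True)
class LineageKey:
    variants: frozenset   # window-clipped VariantCalls
    qualifier: str = ""   # basal haplogroup, only when the clipped set is uninformative


def basal_haplogroup(label: str | None, tree: MotifTree) -> str:
    """First letter-level clade on the root path (e.g. U5b -> U, H1 -> H)."""
    if label is None:
        return ""
    if label == FALLBACK_LABEL:
        return "H"
    if label not in tree.nodes:
        return label
    path = tree.root_path(label)
    # H, V and HV are kept distinct (each has its own coding definition and
    # is separated in the source convention); everything else collapses to
    # the first named clade below the root/R backbone.
    if "H" in path:
        return "H"
    if "V" in path:
        return "V"
    if "HV" in path:
        return "HV"
    for lab in path:
        if lab not in {tree.root, "R"}:
            return lab
    return label


def lineage_key(ind: Individual, window: tuple[int, int],
                tree: MotifTree | None = None) -> LineageKey:
    """Lineage identity of one individual: clipped variants (+ basal qualifier).

    The basal-haplogroup qualifier is attached only when the clipped variant
    set is empty, i.e. when the HVS-I sequence alone cannot separate clades.
    """
    if ind.haplotype is None:
        raise ValueError(f"individual {ind.id} has no haplotype")
    clipped = frozenset(ind.haplotype.clipped(window).variants)
    if clipped:
        return LineageKey(clipped, "")
    tree = tree or MotifTree.default()
    return LineageKey(clipped, basal_haplogroup(ind.haplogroup, tree))


def _group_keys(dataset: Dataset, groups: list[GroupDefinition],
                window: tuple[int, int] | None,
                tree: MotifTree | None) -> dict[str, list[LineageKey]]:
    tree = tree or MotifTree.default()
    out: dict[str, list[LineageKey]] = {}
    windows = [window or dataset.window]
    for g in groups:
        members = [i for i in g.resolve(dataset) if i.haplotype is not None]
        if not members:
            raise ValueError(f"group {g.label} has no sequenced members")
        windows.extend(i.haplotype.window for i in members)
    # Overlap window: intersection across all individuals involved.
    lo = max(w[0] for w in windows)
    hi = min(w[1] for w in windows)
    for g in groups:
        members = [i for i in g.resolve(dataset) if i.haplotype is not None]
        out[g.label] = [lineage_key(i, (lo, hi), tree) for i in members]
    return out


def sha_matrix(dataset: Dataset, groups: list[GroupDefinition],
               window: tuple[int, int] | None = None,
               tree: MotifTree | None = None) -> pd.DataFrame:
    """Percent of column-group individuals whose lineage occurs in the row group."""
    keys = _group_keys(dataset, groups, window, tree)
    labels = [g.label for g in groups]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    lineage_sets = {lab: set(ks) for lab, ks in keys.items()}
    for row in labels:
        for col in labels:
            hits = sum(1 for k in keys[col] if k in lineage_sets[row])
            mat.loc[row, col] = 100.0 * hits / len(keys[col])
    return mat


def ancestral_sha(dataset: Dataset, groups: list[GroupDefinition],
                  window: tuple[int, int] | None = None,
                  tree: MotifTree | None = None) -> pd.DataFrame:
    """First-appearance attribution of each group's lineages.

    Rows are chronologically ordered groups; the entry in an earlier-ranked
    column G' is the percentage of the row group's individuals whose lineage
    first appears in G'; the row group's own (diagonal) entry is the
    percentage of new lineages, absent from every earlier group.  Each row
    sums to 100 and the oldest row is 100% new.  Requires unique ranks.
    """
    ranks = [g.rank for g in groups]
    if any(r is None for r in ranks) or len(set(ranks)) != len(ranks):
        raise ValueError("ancestral SHA needs unique chronological ranks")
    ordered = sorted(groups, key=lambda g: g.rank)
    keys = _group_keys(dataset, ordered, window, tree)
    labels = [g.label for g in ordered]
    lineage_sets = {lab: set(keys[lab]) for lab in labels}
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for gi, lab in enumerate(labels):
        n = len(keys[lab])
        for k in keys[lab]:
            source = next(
                (labels[e] for e in range(gi) if k in lineage_sets[labels[e]]),
                lab)
            mat.loc[lab, source] += 100.0 / n
    return mat
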