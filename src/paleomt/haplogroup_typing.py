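"""Rule-based mtDNA haplogroup classification.

Calls combine two evidence sources, mirroring how ancient-DNA studies type
degraded samples: (i) the HVS-I substitution haplotype scored against a
compact haplogroup motif tree ("phylotree-lite", packaged as editable JSON),
and (ii) multiplex coding-region SNP panels (GenoCoRe22-style basal panel,
H-PLEX17 H-subclade panel, U-Plex and T-Plex) that anchor or refine the
HVS-I call.

Scoring of an HVS-I haplotype against a tree node uses the node's cumulative
root-path motif: +1 for each motif variant present, -1 for each motif variant
expected but absent (positions flagged missing are not penalised); private
variants score 0.  The call is the highest-scoring node, ties broken by depth
(deeper wins) and then lexicographically.  A haplotype providing no positive
motif evidence (including the reference-identical haplotype) receives the
conventional fallback label ``H-rCRS``, which is uninformative below H
without coding SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

from .core_io import CodingSNPProfile, Dataset, HVS1Haplotype, parse_variant

FALLBACK_LABEL = "H-rCRS"

#: Positions whose panel interpretation carries a published caveat (the
#: H1-defining G3010A also occurs in several minor H subclades).
AMBIGUOUS_PANEL_POSITIONS = {3010: "G3010A also reported for H30b/H65a/H79a/H105a"}


@dataclass(frozen=True)
class MotifNode:
    label: str
    parent: str | None
    hvs1_motif: frozenset  # of VariantCall
    coding_diagnostics: frozenset  # of (position, base)


class MotifTree:
    """A validated haplogroup tree with cumulative motif lookup."""

    def __init__(self, nodes: list[MotifNode]):
        self.nodes = {n.label: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate node labels in motif tree")
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError("motif tree must have exactly one root")
        self.root = roots[0].label
        for n in nodes:
            if n.parent is not None and n.parent not in self.nodes:
                raise ValueError(f"node {n.label}: unknown parent {n.parent}")
        # Acyclicity: every node must reach the root.
        for label in self.nodes:
            self.root_path(label)

    def root_path(self, label: str) -> list[str]:
        """Labels from the root down to ``label`` inclusive."""
        path, seen = [], set()
        cur: str | None = label
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in motif tree at {cur}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def depth(self, label: str) -> int:
        return len(self.root_path(label)) - 1

    def cumulative_motif(self, label: str) -> dict[int, str]:
        """Root-path HVS-I motif as position -> expected base (child overrides)."""
        motif: dict[int, str] = {}
        for lab in self.root_path(label):
            for v in self.nodes[lab].hvs1_motif:
                motif[v.position] = v.base
        return motif

    def cumulative_coding(self, label: str) -> dict[int, str]:
        coding: dict[int, str] = {}
        for lab in self.root_path(label):
            for pos, base in self.nodes[lab].coding_diagnostics:
                coding[pos] = base
        return coding

    def is_ancestor_or_equal(self, anc: str, desc: str) -> bool:
        return anc in self.root_path(desc)

    def same_root_path(self, a: str, b: str) -> bool:
        return self.is_ancestor_or_equal(a, b) or self.is_ancestor_or_equal(b, a)

    @classmethod
    def from_json(cls, source) -> "MotifTree":
        data = json.loads(source) if isinstance(source, str) else json.load(source)
        nodes = [
            MotifNode(
                label=n["label"],
                parent=n["parent"],
                hvs1_motif=frozenset(parse_variant(tok) for tok in n["hvs1"]),
                coding_diagnostics=frozenset((int(p), b) for p, b in n["coding"]),
            )
            for n in data["nodes"]
        ]
        return cls(nodes)

    @classmethod
    def default(cls) -> "MotifTree":
        with resources.files("paleomt.data").joinpath("motif_tree.json").open() as fh:
            return cls.from_json(fh)


@dataclass(frozen=True)
class PanelEntry:
    position: int
    ref: str
    alt: str
    haplogroup: str


@dataclass
class PanelConfig:
    """One multiplex assay: assayed positions and the clade each derived allele supports."""

    name: str
    entries: list[PanelEntry]

    def __post_init__(self):
        expected = {"GenoCoRe22": 22, "H-PLEX17": 17}
        if self.name in expected and len(self.entries) != expected[self.name]:
            raise ValueError(
                f"panel {self.name} must have {expected[self.name]} entries, "
                f"got {len(self.entries)}")
        if self.name == "T-Plex":
            pairs = {(e.position, e.alt, e.haplogroup) for e in self.entries}
            if (12633, "A", "T1") not in pairs or (11812, "G", "T2") not in pairs:
                raise ValueError("T-Plex must include C12633A->T1 and A11812G->T2")

    @property
    def positions(self) -> set[int]:
        return {e.position for e in self.entries}


def load_panels(source=None) -> dict[str, PanelConfig]:
    if source is None:
        with resources.files("paleomt.data").joinpath("panels.json").open() as fh:
            data = json.load(fh)
    else:
        data = json.loads(source) if isinstance(source, str) else json.load(source)
    return {
        name: PanelConfig(name, [
            PanelEntry(int(e["position"]), e["ref"], e["alt"], e["haplogroup"])
            for e in entries
        ])
        for name, entries in data["panels"].items()
    }


@dataclass
class HaplogroupCall:
    label: str
    matched: int = 0
    private: int = 0
    basis: set = field(default_factory=set)
    consistent: bool = True
    caveats: list = field(default_factory=list)


def call_from_hvs1(hap: HVS1Haplotype, tree: MotifTree) -> HaplogroupCall:
    """Score the haplotype against every tree node and return the best call.

    Invariant under variant-set permutation and under addition of private
    (non-motif) variants.  Haplotypes without positive motif evidence fall
    back to ``H-rCRS``.
    """
    if not tree.nodes:
        raise ValueError("empty motif tree")
    observed = {v.position: v.base for v in hap.variants}
    best: tuple[int, int, str] | None = None  # (score, depth, label) to maximise
    best_matched = 0
    for label in tree.nodes:
        motif = tree.cumulative_motif(label)
        matched = sum(1 for p, b in motif.items() if observed.get(p) == b)
        absent = sum(
            1 for p, b in motif.items()
            if observed.get(p) != b and p not in hap.missing)
        score = matched - absent
        key = (score, tree.depth(label), _lex_key(label))
        if best is None or key > best:
            best, best_matched = key, matched
    assert best is not None
    if best[0] <= 0:
        return HaplogroupCall(FALLBACK_LABEL, 0, len(hap.variants), {"HVS1"})
    label = best[2].key  # unwrap
    return HaplogroupCall(label, best_matched, len(hap.variants) - best_matched, {"HVS1"})


class _lex_key:
    """Reversed lexicographic comparison so that max() prefers the smaller label."""

    __slots__ = ("key",)

    def __init__(self, key: str):
        self.key = key

    def __lt__(self, other):
        return self.key > other.key

    def __gt__(self, other):
        return self.key < other.key

    def __eq__(self, other):
        return self.key == other.key


def _supported_labels(profile: CodingSNPProfile,
                      panels: dict[str, PanelConfig],
                      tree: MotifTree) -> tuple[list[str], list[str]]:
    """Tree labels supported by derived panel alleles, plus caveat notes."""
    supported, caveats = [], []
    observed = profile.observed()
    for panel in panels.values():
        for entry in panel.entries:
            if observed.get(entry.position) == entry.alt and entry.haplogroup in tree.nodes:
                supported.append(entry.haplogroup)
                if entry.position in AMBIGUOUS_PANEL_POSITIONS:
                    caveats.append(AMBIGUOUS_PANEL_POSITIONS[entry.position])
    # Deterministic order: shallow to deep, then lexicographic.
    supported.sort(key=lambda lab: (tree.depth(lab), lab))
    return supported, caveats


def refine_with_panel(call: HaplogroupCall, profile: CodingSNPProfile,
                      panels: dict[str, PanelConfig], tree: MotifTree) -> HaplogroupCall:
    """Refine (or contradict) an HVS-I call with coding-panel evidence.

    A panel-supported subclade replaces a compatible ancestor label; support
    for a clade on a different root-path flags the call inconsistent.  Missing
    panel calls degrade gracefully.
    """
    supported, caveats = _supported_labels(profile, panels, tree)
    label = call.label
    consistent = call.consistent
    anchor = None if label == FALLBACK_LABEL else label
    for lab in supported:
        if anchor is None:
            anchor = lab
        elif tree.is_ancestor_or_equal(anchor, lab):
            anchor = lab  # refinement down the same path
        elif tree.is_ancestor_or_equal(lab, anchor):
            pass  # ancestral confirmation
        else:
            consistent = False
    new_label = anchor if anchor is not None else label
    return replace(
        call, label=new_label, basis=set(call.basis) | {"SNP-panel"},
        consistent=consistent, caveats=list(call.caveats) + caveats)


def call_from_panel(profile: CodingSNPProfile, panels: dict[str, PanelConfig],
                    tree: MotifTree) -> HaplogroupCall:
    """Panel-only call for individuals without a reproducible HVS-I haplotype."""
    supported, caveats = _supported_labels(profile, panels, tree)
    label, consistent = None, True
    for lab in supported:
        if label is None or tree.is_ancestor_or_equal(label, lab):
            label = lab
        elif tree.is_ancestor_or_equal(lab, label):
            pass
        else:
            consistent = False
    return HaplogroupCall(label or FALLBACK_LABEL, 0, 0, {"SNP-panel"},
                          consistent, caveats)


def classify_dataset(dataset: Dataset, tree: MotifTree | None = None,
                     panels: dict[str, PanelConfig] | None = None,
                     ) -> tuple[Dataset, pd.DataFrame]:
    """Label every individual; returns the labelled dataset plus a report.

    The report (one row per individual) records the call, evidence basis,
    matched/private variant counts, the consistency flag and any caveats.
    """
    tree = tree or MotifTree.default()
    panels = panels if panels is not None else load_panels()
    new_individuals, rows = [], []
    for ind in dataset.individuals:
        if ind.haplotype is None and ind.snp_profile is None:
            call = HaplogroupCall("unresolved", consistent=False)
        elif ind.haplotype is None:
            call = call_from_panel(ind.snp_profile, panels, tree)
        else:
            call = call_from_hvs1(ind.haplotype, tree)
            if ind.snp_profile is not None:
                call = refine_with_panel(call, ind.snp_profile, panels, tree)
        new_individuals.append(replace(ind, haplogroup=call.label))
        rows.append({
            "id": ind.id, "haplogroup": call.label,
            "basis": "+".join(sorted(call.basis)),
            "matched": call.matched, "private": call.private,
            "consistent": call.consistent,
            "caveats": "; ".join(call.caveats),
        })
    report = pd.DataFrame(rows)
    return dataset.with_individuals(new_individuals), report
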