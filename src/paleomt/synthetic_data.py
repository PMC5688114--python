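"""Seeded generator of serial, regionally structured HVS-I datasets.

The generator emulates the statistical structure the diachronic analyses
assume: chronologically ordered groups with haplogroup pools (a U-dominated
hunter-gatherer pool vs. a farmer pool of K/J/T2/H/N1a/V/X lineages),
haplogroup-frequency drift between consecutive groups (via the same
Wright–Fisher kernel the continuity test uses), and lineage transmission —
a configurable fraction of each group's individuals carry a haplotype copied
verbatim from an earlier group, which is what shared-haplotype analyses
measure.

Each generated individual gets: the cumulative HVS-I motif of its
haplogroup, plus Poisson(λ) private transitions at uniformly chosen
non-motif window positions (transitions only, reflecting the strong
transition bias of the control region; default λ = 0.8, giving the
many-singleton haplotype spectra typical of HVS-I data), and a coding-SNP
profile consistent with its haplogroup's diagnostics.

With a fixed seed the output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .continuity import wf_drift
from .core_io import (DEFAULT_WINDOW, CodingSNPProfile, Dataset, HVS1Haplotype,
                      Individual, ReferenceSegment, VariantCall)
from .haplogroup_typing import MotifTree, PanelConfig, load_panels

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

DEFAULT_PRIVATE_RATE = 0.8


@dataclass
class SyntheticGroupSpec:
    """One serial group: size, haplogroup pool, drift link and lineage copying.

    ``freqs`` gives the haplogroup frequency vector for fresh draws; for
    drift-derived groups it is computed as wf_drift(parent freqs, Ne, t).
    ``lineage_copy`` lists (source group label, fraction): each individual
    independently copies a complete haplotype from a realized member of the
    source group with the given probability, which is the lineage-sharing
    signal SHA recovers.
    """

    label: str
    n: int
    freqs: dict[str, float] | None = None
    parent: tuple[str, int, int] | None = None  # (label, Ne, generations)
    lineage_copy: list[tuple[str, float]] = field(default_factory=list)
    private_rate: float = DEFAULT_PRIVATE_RATE
    region: str = "OTHER"
    period: str = "NEO"

    def __post_init__(self):
        if self.freqs is None and self.parent is None:
            raise ValueError(f"group {self.label}: needs freqs or a parent link")
        if self.freqs is not None:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {self.label}: frequencies sum to {total}")
        if self.private_rate < 0:
            raise ValueError("private-mutation rate must be >= 0")
        if sum(f for _, f in self.lineage_copy) > 1.0 + 1e-12:
            raise ValueError(f"group {self.label}: copy fractions exceed 1")


@dataclass
class SyntheticDatasetConfig:
    groups: list[SyntheticGroupSpec]
    seed: int = 0
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        seen: set[str] = set()
        for g in self.groups:
            for src in [g.parent[0]] if g.parent else []:
                if src not in seen:
                    raise ValueError(
                        f"group {g.label}: parent {src} must precede it (acyclic order)")
            for src, _ in g.lineage_copy:
                if src not in seen:
                    raise ValueError(
                        f"group {g.label}: copy source {src} must precede it")
            seen.add(g.label)


def generate_individual(ident: str, haplogroup: str, tree: MotifTree,
                        private_rate: float, rng: np.random.Generator,
                        reference: ReferenceSegment,
                        window: tuple[int, int] = DEFAULT_WINDOW,
                        panels: dict[str, PanelConfig] | None = None,
                        region: str = "OTHER", period: str = "NEO") -> Individual:
    """One individual of the given haplogroup with Poisson private transitions."""
    if haplogroup not in tree.nodes:
        raise ValueError(f"unknown haplogroup {haplogroup!r}")
    motif = tree.cumulative_motif(haplogroup)
    variants = {pos: base for pos, base in motif.items()
                if window[0] <= pos <= window[1]}
    # Private transitions avoid every motif position in the tree so that
    # classification is invariant to them.
    reserved = {p for lab in tree.nodes for p in tree.cumulative_motif(lab)}
    candidates = np.array([p for p in range(window[0], window[1] + 1)
                           if p not in reserved])
    k = rng.poisson(private_rate)
    for pos in rng.choice(candidates, size=min(k, len(candidates)), replace=False):
        ref_base = reference.base_at(int(pos))
        variants[int(pos)] = _TRANSITION[ref_base]
    hap = HVS1Haplotype(
        frozenset(VariantCall(p, b) for p, b in variants.items()), window)

    panels = panels if panels is not None else load_panels()
    coding = tree.cumulative_coding(haplogroup)
    calls: dict[int, str | None] = {}
    for panel in panels.values():
        for entry in panel.entries:
            on_path = (entry.haplogroup in tree.nodes
                       and coding.get(entry.position) == entry.alt
                       and tree.is_ancestor_or_equal(entry.haplogroup, haplogroup))
            calls[entry.position] = entry.alt if on_path else entry.ref
    return Individual(id=ident, region=region, period=period, haplotype=hap,
                      snp_profile=CodingSNPProfile(calls),
                      extra={"true_haplogroup": haplogroup})


def _resolve_freqs(spec: SyntheticGroupSpec,
                   resolved: dict[str, tuple[list[str], np.ndarray]],
                   rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    if spec.freqs is not None:
        cats = list(spec.freqs)
        return cats, np.array([spec.freqs[c] for c in cats], dtype=float)
    parent_label, ne, gens = spec.parent
    cats, parent_f = resolved[parent_label]
    return cats, wf_drift(parent_f, ne, gens, rng)


def generate_transect(cfg: SyntheticDatasetConfig,
                      tree: MotifTree | None = None,
                      reference: ReferenceSegment | None = None,
                      panels: dict[str, PanelConfig] | None = None) -> Dataset:
    """Generate the full serial dataset described by ``cfg`` (deterministic)."""
    tree = tree or MotifTree.default()
    reference = reference or ReferenceSegment.default()
    panels = panels if panels is not None else load_panels()
    rng = np.random.default_rng(cfg.seed)
    individuals: list[Individual] = []
    realized: dict[str, list[Individual]] = {}
    freq_cache: dict[str, tuple[list[str], np.ndarray]] = {}
    for spec in cfg.groups:
        cats, freqs = _resolve_freqs(spec, freq_cache, rng)
        freq_cache[spec.label] = (cats, freqs)
        members: list[Individual] = []
        copy_sources = [s for s, _ in spec.lineage_copy]
        copy_probs = np.array([f for _, f in spec.lineage_copy], dtype=float)
        for i in range(spec.n):
            ident = f"{spec.label}_{i:03d}"
            u = rng.random()
            edges = np.cumsum(copy_probs)
            src = next((copy_sources[j] for j, e in enumerate(edges) if u < e), None)
            if src is not None:
                donor = realized[src][rng.integers(len(realized[src]))]
                ind = Individual(
                    id=ident, region=spec.region, period=spec.period,
                    haplotype=donor.haplotype, snp_profile=donor.snp_profile,
                    extra={"true_haplogroup": donor.extra["true_haplogroup"],
                           "copied_from": donor.id})
            else:
                hg = cats[rng.choice(len(cats), p=freqs / freqs.sum())]
                ind = generate_individual(ident, hg, tree, spec.private_rate,
                                          rng, reference, cfg.window, panels,
                                          spec.region, spec.period)
            members.append(ind)
        realized[spec.label] = members
        individuals.extend(members)
    return Dataset(individuals, reference, cfg.window)


def default_transect_config(seed: int = 0) -> SyntheticDatasetConfig:
    """Packaged study-like design: a hunter-gatherer pool, an Early Neolithic
    farmer pool, drift-derived later periods with lineage inheritance and a
    small hunter-gatherer admixture fraction; group sizes follow the kind of
    serial sampling the analyses target (35/27/74/118/16)."""
    hg_pool = {"U5b": 0.55, "U5a": 0.25, "U4": 0.12, "U2": 0.08}
    en_pool = {"K": 0.20, "J": 0.15, "T2": 0.12, "H": 0.18, "H1": 0.05,
               "N1a": 0.04, "V": 0.10, "X": 0.06, "HV": 0.05, "U3": 0.05}
    groups = [
        SyntheticGroupSpec("HG", 35, freqs=hg_pool, region="OTHER", period="HG"),
        SyntheticGroupSpec("EN", 27, freqs=en_pool, region="NEI", period="EN"),
        SyntheticGroupSpec("MLN", 74, parent=("EN", 1000, 60),
                           lineage_copy=[("EN", 0.45), ("HG", 0.07)],
                           region="NEI", period="MLN"),
        SyntheticGroupSpec("CHA", 118, parent=("MLN", 1000, 32),
                           lineage_copy=[("MLN", 0.15), ("EN", 0.30), ("HG", 0.05)],
                           region="CI", period="CHA"),
        SyntheticGroupSpec("EBA", 16, parent=("CHA", 1000, 28),
                           lineage_copy=[("CHA", 0.35), ("MLN", 0.10), ("EN", 0.20)],
                           region="SEI", period="EBA"),
    ]
    return SyntheticDatasetConfig(groups, seed=seed)
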