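"""Data model and IO for serial ancient-mtDNA HVS-I datasets.

Coordinates are rCRS, 1-based; windows are inclusive on both ends.  Three
windows recur in this kind of study and are per-analysis configuration:
16048-16410 (diversity indices), 16056-16390 (distance/sharing analyses,
the package default) and 16068-16365 (comparisons against heterogeneous
modern data).  Only single-nucleotide substitutions are modelled; indels and
heteroplasmies are ignored, and positions read as N or gap are tracked as
*missing* so pairwise statistics can use pairwise deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import build_reference

REGIONS = {"NEI", "SEI", "SWI", "CI", "OTHER"}
PERIODS = {"HG", "EN", "MLN", "NEO", "ECHA", "LCHA", "CHA", "EBA"}

#: Umbrella period labels expand to their members when used in a group filter;
#: imprecisely dated individuals carry the umbrella label itself.
UMBRELLA_PERIODS = {
    "NEO": {"EN", "MLN", "NEO"},
    "CHA": {"ECHA", "LCHA", "CHA"},
}

DEFAULT_WINDOW = (16056, 16390)
DIVERSITY_WINDOW = (16048, 16410)
MODERN_WINDOW = (16068, 16365)

_BASES = frozenset("ACGT")
_VARIANT_RE = re.compile(r"^(\d+)([ACGTacgt])$")


@dataclass(frozen=True, order=True)
class VariantCall:
    """A single substitution relative to the reference: rCRS position + observed base."""

    position: int
    base: str

    def __post_init__(self):
        if self.base not in _BASES:
            raise ValueError(f"invalid base {self.base!r} at {self.position}")

    def __str__(self) -> str:
        return f"{self.position}{self.base}"


def parse_variant(token: str, window: tuple[int, int] | None = None,
                  reference: "ReferenceSegment | None" = None) -> VariantCall:
    """Parse a ``<position><base>`` token such as ``16270T``.

    Indel/heteroplasmy tokens (``16189.1C``, ``16166d``, IUPAC ambiguity
    codes) are rejected: the data model is substitution-only.  When a window
    or reference is supplied the position must fall inside the window and the
    base must differ from the reference base.
    """
    m = _VARIANT_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed variant token {token!r} (expected <digits><ACGT>)")
    pos, base = int(m.group(1)), m.group(2).upper()
    if window is not None and not (window[0] <= pos <= window[1]):
        raise ValueError(f"variant {token!r} outside window {window[0]}-{window[1]}")
    if reference is not None:
        ref_base = reference.base_at(pos)
        if ref_base == base:
            raise ValueError(f"variant {token!r} equals the reference base {ref_base}")
    return VariantCall(pos, base)


@dataclass(frozen=True)
class ReferenceSegment:
    """A reference sequence string anchored at a 1-based rCRS start coordinate."""

    sequence: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def covers(self, window: tuple[int, int]) -> bool:
        return self.start <= window[0] and window[1] <= self.end

    def base_at(self, pos: int) -> str:
        if not (self.start <= pos <= self.end):
            raise ValueError(f"position {pos} outside reference {self.start}-{self.end}")
        return self.sequence[pos - self.start]

    @classmethod
    def default(cls) -> "ReferenceSegment":
        seq, start = build_reference()
        return cls(seq, start)


@dataclass(frozen=True)
class HVS1Haplotype:
    """A set of substitutions inside an HVS-I window, plus missing positions.

    ``missing`` holds positions that could not be read (N or gap in the
    consensus); a missing position is never a variant.
    """

    variants: frozenset[VariantCall] = frozenset()
    window: tuple[int, int] = DEFAULT_WINDOW
    missing: frozenset[int] = frozenset()

    def __post_init__(self):
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate variant positions in haplotype")
        lo, hi = self.window
        for v in self.variants:
            if not (lo <= v.position <= hi):
                raise ValueError(f"variant {v} outside window {lo}-{hi}")
        bad = {v.position for v in self.variants} & set(self.missing)
        if bad:
            raise ValueError(f"positions both variant and missing: {sorted(bad)}")

    @property
    def sorted_variants(self) -> tuple[VariantCall, ...]:
        """Variants in canonical (position) order."""
        return tuple(sorted(self.variants))

    def clipped(self, window: tuple[int, int]) -> "HVS1Haplotype":
        """Restrict to the intersection of ``window`` with the current window."""
        lo = max(window[0], self.window[0])
        hi = min(window[1], self.window[1])
        return HVS1Haplotype(
            frozenset(v for v in self.variants if lo <= v.position <= hi),
            (lo, hi),
            frozenset(p for p in self.missing if lo <= p <= hi),
        )

    def __str__(self) -> str:
        return " ".join(str(v) for v in self.sorted_variants) or "rCRS"


def variants_from_sequence(seq: str, reference: ReferenceSegment,
                           window: tuple[int, int] = DEFAULT_WINDOW) -> HVS1Haplotype:
    """Diff a pre-aligned sequence against the reference inside ``window``.

    ``seq`` must have the same length as the reference segment (one column per
    reference position; the alignment is assumed gap-free in the reference).
    N or gap columns are recorded as missing positions, not variants.
    """
    if len(seq) != len(reference.sequence):
        raise ValueError(
            f"sequence length {len(seq)} != reference length {len(reference.sequence)}")
    if not reference.covers(window):
        raise ValueError(f"reference {reference.start}-{reference.end} does not cover {window}")
    variants, missing = set(), set()
    lo, hi = window
    for pos in range(lo, hi + 1):
        obs = seq[pos - reference.start].upper()
        ref = reference.sequence[pos - reference.start]
        if obs in _BASES:
            if obs != ref:
                variants.add(VariantCall(pos, obs))
        else:
            missing.add(pos)
    return HVS1Haplotype(frozenset(variants), window, frozenset(missing))


def sequence_from_variants(hap: HVS1Haplotype, reference: ReferenceSegment,
                           window: tuple[int, int] | None = None) -> str:
    """Reconstruct the full-segment sequence carrying the haplotype's variants.

    Round-trip property: ``variants_from_sequence(sequence_from_variants(h))``
    equals ``h`` for any valid haplotype without missing data.
    """
    window = window or hap.window
    if not reference.covers(window):
        raise ValueError(f"reference {reference.start}-{reference.end} does not cover {window}")
    seq = list(reference.sequence)
    for v in hap.variants:
        if not (reference.start <= v.position <= reference.end):
            raise ValueError(f"variant {v} outside reference coverage")
        seq[v.position - reference.start] = v.base
    for pos in hap.missing:
        seq[pos - reference.start] = "N"
    return "".join(seq)


@dataclass
class CodingSNPProfile:
    """Observed bases at assayed coding-region positions (``None`` = no call)."""

    calls: dict[int, str | None] = field(default_factory=dict)

    def observed(self) -> dict[int, str]:
        return {p: b for p, b in self.calls.items() if b is not None}

    def __str__(self) -> str:
        return ";".join(f"{p}{b}" for p, b in sorted(self.observed().items()))

    @classmethod
    def from_string(cls, text: str) -> "CodingSNPProfile":
        calls: dict[int, str | None] = {}
        for tok in text.split(";"):
            tok = tok.strip()
            if not tok:
                continue
            m = _VARIANT_RE.match(tok)
            if not m:
                raise ValueError(f"malformed coding SNP token {tok!r}")
            calls[int(m.group(1))] = m.group(2).upper()
        return cls(calls)


@dataclass
class Individual:
    """One sampled person: identity, provenance, haplotype and typing results."""

    id: str
    site: str = ""
    region: str = "OTHER"
    period: str = "NEO"
    haplotype: HVS1Haplotype | None = None
    snp_profile: CodingSNPProfile | None = None
    haplogroup: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r} for {self.id}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r} for {self.id}")


@dataclass
class GroupDefinition:
    """A chronological/geographic grouping of individuals.

    Membership is an explicit id list if given, otherwise the pure filter
    region ∈ regions AND period ∈ periods (umbrella periods expand).  ``rank``
    orders groups chronologically for ancestral sharing analyses.
    """

    label: str
    regions: set[str] | None = None
    periods: set[str] | None = None
    member_ids: list[str] | None = None
    rank: int | None = None

    def expanded_periods(self) -> set[str] | None:
        if self.periods is None:
            return None
        out: set[str] = set()
        for p in self.periods:
            out |= UMBRELLA_PERIODS.get(p, {p})
        return out

    def resolve(self, dataset: "Dataset") -> list[Individual]:
        if self.member_ids is not None:
            index = {ind.id: ind for ind in dataset.individuals}
            missing = [i for i in self.member_ids if i not in index]
            if missing:
                raise KeyError(f"group {self.label}: unknown ids {missing}")
            return [index[i] for i in self.member_ids]
        periods = self.expanded_periods()
        out = [
            ind for ind in dataset.individuals
            if (self.regions is None or ind.region in self.regions)
            and (periods is None or ind.period in periods)
        ]
        return out


@dataclass
class Dataset:
    """All individuals plus the reference segment and the analysis window."""

    individuals: list[Individual] = field(default_factory=list)
    reference: ReferenceSegment = field(default_factory=ReferenceSegment.default)
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate individual ids: {sorted(dupes)}")
        if not self.reference.covers(self.window):
            raise ValueError("reference segment does not cover the dataset window")

    def by_id(self, ident: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ident:
                return ind
        raise KeyError(ident)

    def with_individuals(self, individuals: list[Individual]) -> "Dataset":
        return Dataset(individuals, self.reference, self.window)

    def sequences(self, window: tuple[int, int] | None = None) -> dict[str, str]:
        """Reconstructed window-clipped sequence strings for every individual
        with a haplotype (missing positions rendered as N)."""
        window = window or self.window
        out = {}
        for ind in self.individuals:
            if ind.haplotype is None:
                continue
            full = sequence_from_variants(ind.haplotype, self.reference)
            lo = window[0] - self.reference.start
            hi = window[1] - self.reference.start + 1
            out[ind.id] = full[lo:hi]
        return out


# ---------------------------------------------------------------------------
# Tabular / FASTA IO

_CORE_COLUMNS = ["id", "site", "region", "period", "haplogroup", "haplotype", "missing", "snps"]


def read_metadata_table(path, reference: ReferenceSegment | None = None,
                        window: tuple[int, int] = DEFAULT_WINDOW) -> Dataset:
    """Read a per-individual metadata TSV into a Dataset.

    Required columns: id, region, period.  The haplotype column holds
    space-separated variant tokens or the literal ``rCRS``; ``missing`` holds
    space-separated unreadable positions; ``snps`` holds ``pos+base`` tokens
    joined by ``;``.  Unknown columns are preserved per individual.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("id", "region", "period"):
        if col not in df.columns:
            raise ValueError(f"metadata table missing required column {col!r}")
    reference = reference or ReferenceSegment.default()
    extra_cols = [c for c in df.columns if c not in _CORE_COLUMNS]
    individuals = []
    for _, row in df.iterrows():
        hap = None
        if "haplotype" in df.columns and row["haplotype"].strip():
            text = row["haplotype"].strip()
            variants = frozenset() if text == "rCRS" else frozenset(
                parse_variant(tok, window, reference) for tok in text.split())
            miss = frozenset(
                int(t) for t in row.get("missing", "").split()) if "missing" in df.columns else frozenset()
            hap = HVS1Haplotype(variants, window, miss)
        profile = None
        if "snps" in df.columns and row["snps"].strip():
            profile = CodingSNPProfile.from_string(row["snps"])
        individuals.append(Individual(
            id=row["id"], site=row.get("site", ""),
            region=row["region"], period=row["period"],
            haplotype=hap, snp_profile=profile,
            haplogroup=row.get("haplogroup", "") or None,
            extra={c: row[c] for c in extra_cols},
        ))
    return Dataset(individuals, reference, window)


def write_metadata_table(dataset: Dataset, path) -> None:
    """Serialize a Dataset to TSV; inverse of :func:`read_metadata_table`."""
    rows = []
    extra_cols: list[str] = []
    for ind in dataset.individuals:
        for c in ind.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    for ind in dataset.individuals:
        row = {
            "id": ind.id, "site": ind.site, "region": ind.region, "period": ind.period,
            "haplogroup": ind.haplogroup or "",
            "haplotype": str(ind.haplotype) if ind.haplotype is not None else "",
            "missing": " ".join(str(p) for p in sorted(ind.haplotype.missing))
            if ind.haplotype is not None else "",
            "snps": str(ind.snp_profile) if ind.snp_profile is not None else "",
        }
        row.update({c: ind.extra.get(c, "") for c in extra_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=_CORE_COLUMNS + extra_cols).to_csv(path, sep="\t", index=False)


def read_fasta(path, reference: ReferenceSegment | None = None,
               window: tuple[int, int] = DEFAULT_WINDOW) -> dict[str, HVS1Haplotype]:
    """Read pre-aligned consensus sequences (record id = individual id)."""
    reference = reference or ReferenceSegment.default()
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = variants_from_sequence(str(rec.seq), reference, window)
    return out


def write_fasta(dataset: Dataset, path) -> None:
    """Write every haplotype-bearing individual as a full-segment FASTA record."""
    records = [
        SeqRecord(Seq(sequence_from_variants(ind.haplotype, dataset.reference)),
                  id=ind.id, description="")
        for ind in dataset.individuals if ind.haplotype is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def attach_haplotypes(dataset: Dataset, haplotypes: dict[str, HVS1Haplotype]) -> Dataset:
    """Return a dataset with FASTA-derived haplotypes attached by id."""
    new = []
    for ind in dataset.individuals:
        if ind.id in haplotypes:
            ind = replace(ind, haplotype=haplotypes[ind.id])
        new.append(ind)
    return dataset.with_individuals(new)
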