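"""Synthetic HVS-I reference segment in rCRS coordinates.

The analyses in this package are defined on substitution haplotypes relative
to the revised Cambridge Reference Sequence (rCRS).  The genuine rCRS
sequence is not redistributed here; instead a *synthetic* stand-in segment is
generated deterministically.  Every position that any packaged haplogroup
motif, panel diagnostic, or standard HVS-I variant notation refers to carries
the true rCRS allele (e.g. C at 16270, so that the U5 motif variant "16270T"
is a substitution, as in the standard notation).  All other positions are
filled with a fixed pseudo-random base.

Because every statistic in the package operates on variant sets *relative* to
the reference (or on pairwise sequence differences), results are invariant to
the filler bases; the stand-in only has to be internally consistent, which it
is by construction (fixed internal seed, byte-identical across runs).
"""

from __future__ import annotations

import numpy as np

# Start/end of the generated segment (inclusive, rCRS 1-based coordinates).
REF_START = 16001
REF_END = 16420

# True rCRS alleles at positions used by motif notation / diagnostics.
# "16270T" notation implies the rCRS base at 16270 is C, etc.
RCRS_KNOWN_BASES: dict[int, str] = {
    16051: "A",  # 16051G -> U2
    16069: "C",  # 16069T -> J
    16126: "T",  # 16126C -> J / T
    16129: "G",
    16147: "C",  # 16147A -> N1a
    16163: "A",  # 16163G -> T1
    16172: "T",  # 16172C
    16186: "C",  # 16186T -> T1
    16187: "C",  # 16187T -> L1b
    16189: "T",  # 16189C
    16192: "C",
    16209: "T",
    16213: "G",
    16223: "C",  # 16223T -> N/M
    16224: "T",  # 16224C -> K
    16230: "A",
    16234: "C",
    16243: "T",
    16248: "C",  # 16248T -> N1a
    16256: "C",  # 16256T -> U5a
    16264: "C",  # 16264T -> L1b
    16270: "C",  # 16270T -> U5
    16278: "C",  # 16278T -> X
    16292: "C",  # 16292T -> W
    16294: "C",  # 16294T -> T
    16296: "C",  # 16296T -> T2
    16298: "T",  # 16298C -> V
    16304: "T",
    16311: "T",  # 16311C
    16319: "G",
    16342: "T",  # 16342C -> U8
    16343: "A",  # 16343G -> U3
    16355: "C",  # 16355T -> N1a
    16356: "T",  # 16356C -> U4
    16362: "T",
    16390: "G",
    16399: "A",
}

_FILLER_SEED = 16569  # fixed: the reference must be byte-identical across runs

_BASES = np.array(list("ACGT"))


def build_reference(start: int = REF_START, end: int = REF_END) -> tuple[str, int]:
    """Return ``(sequence, start)`` for the synthetic reference segment.

    ``sequence[i]`` is the base at rCRS position ``start + i``; the segment
    covers ``start..end`` inclusive.
    """
    if not (REF_START <= start <= end <= REF_END):
        raise ValueError(f"requested segment {start}-{end} outside {REF_START}-{REF_END}")
    rng = np.random.default_rng(_FILLER_SEED)
    full = _BASES[rng.integers(0, 4, REF_END - REF_START + 1)]
    for pos, base in RCRS_KNOWN_BASES.items():
        full[pos - REF_START] = base
    lo, hi = start - REF_START, end - REF_START + 1
    return "".join(full[lo:hi]), start
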