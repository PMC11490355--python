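"""Trinucleotide-context encoding shared across the package.

Mutations are classified into the standard 96 single-base-substitution
channels: the mutated base collapsed to the pyrimidine strand (C or T),
6 substitution types x 16 flanking-base combinations.  The same collapsed
encoding drives the genome site census used for context-adjusted expected
counts, so observed and expected live on identical coordinates.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE2CODE = {b: i for i, b in enumerate(BASES)}
_BASE2CODE.update({b.lower(): i for i, b in enumerate(BASES)})

#: substitution types on the pyrimidine strand, canonical order
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_SUB2IDX = {s: i for i, s in enumerate(SUB_TYPES)}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode_seq(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0, C=1, G=2, T=3; other -> 255)."""
    table = np.full(256, 255, dtype=np.uint8)
    for b, c in _BASE2CODE.items():
        table[ord(b)] = c
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def collapse_context(context: str, ref: str, alt: str) -> tuple[str, str]:
    """Collapse a (context, ref>alt) pair onto the pyrimidine strand.

    Returns ``(pyrimidine_context, substitution)`` where the substitution is
    one of :data:`SUB_TYPES`.  Purine-centred inputs are reverse-complemented;
    pyrimidine-centred inputs pass through, so the map is idempotent.
    """
    context = context.upper()
    ref, alt = ref.upper(), alt.upper()
    if context[1] != ref:
        raise ValueError(f"context {context!r} centre does not match ref {ref!r}")
    if ref in "AG":
        context = revcomp(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return context, f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# 96-channel indexing
# ---------------------------------------------------------------------------

def sbs96_labels() -> list[str]:
    """The 96 channel labels in canonical order, e.g. ``A[C>A]A``."""
    labels = []
    for sub in SUB_TYPES:
        centre = sub[0]
        for left in BASES:
            for right in BASES:
                labels.append(f"{left}[{sub}]{right}")
    return labels


SBS96_LABELS = sbs96_labels()
_LABEL2IDX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def sbs96_index(context_pyr: str, substitution: str) -> int:
    """Channel index for a pyrimidine-collapsed context and substitution."""
    left, right = context_pyr[0], context_pyr[2]
    return _SUB2IDX[substitution] * 16 + _BASE2CODE[left] * 4 + _BASE2CODE[right]


def sbs96_label(index: int) -> str:
    return SBS96_LABELS[index]


def context32_index(context_pyr: str) -> int:
    """Index into the 32 collapsed trinucleotide contexts (2 centres x 16)."""
    centre = 0 if context_pyr[1] == "C" else 1
    return centre * 16 + _BASE2CODE[context_pyr[0]] * 4 + _BASE2CODE[context_pyr[2]]


def context32_of_channel(channel: int) -> int:
    """Map an SBS96 channel to its collapsed context index (0..31)."""
    sub, flank = divmod(channel, 16)
    centre = 0 if sub < 3 else 1
    return centre * 16 + flank


CONTEXT32_LABELS = [
    f"{l}{c}{r}" for c in "CT" for l in BASES for r in BASES
]


def classes_for(spec: str) -> np.ndarray:
    """Resolve a substitution-class filter to SBS96 channel indices.

    Accepted forms:

    - ``"all"`` — every channel;
    - a pyrimidine substitution such as ``"T>G"`` (purine spellings are
      collapsed, so ``"A>C"`` works too) — its 16 flank channels;
    - ``"CpG>GpG"`` — C>G at CpG contexts (3' neighbour G);
    - ``"CpG_transversion"`` — C>G and C>A at CpG contexts;
    - an explicit channel label such as ``"A[C>A]G"``.
    """
    if spec == "all":
        return np.arange(96)
    if spec in _LABEL2IDX:
        return np.array([_LABEL2IDX[spec]])
    if spec == "CpG>GpG":
        return np.array([sbs96_index(f"{l}CG", "C>G") for l in BASES])
    if spec == "CpG_transversion":
        return np.array(
            [sbs96_index(f"{l}CG", s) for s in ("C>G", "C>A") for l in BASES]
        )
    if len(spec) == 3 and spec[1] == ">":
        ref, alt = spec[0].upper(), spec[2].upper()
        if ref in "AG":
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        sub = f"{ref}>{alt}"
        if sub not in _SUB2IDX:
            raise ValueError(f"not a substitution: {spec!r}")
        return np.arange(16) + _SUB2IDX[sub] * 16
    raise ValueError(f"unrecognised class filter {spec!r}")


# ---------------------------------------------------------------------------
# Vectorised genome census
# ---------------------------------------------------------------------------

def context_codes(codes: np.ndarray) -> np.ndarray:
    """Per-position collapsed context index (0..31) for a coded sequence.

    Positions 0 and L-1 (no flank) and positions whose 3-mer contains a
    non-ACGT base get -1.
    """
    L = codes.shape[0]
    out = np.full(L, -1, dtype=np.int64)
    if L < 3:
        return out
    left = codes[:-2].astype(np.int64)
    centre = codes[1:-1].astype(np.int64)
    right = codes[2:].astype(np.int64)
    valid = (left < 4) & (centre < 4) & (right < 4)
    # pyrimidine collapse: centre A/G -> reverse complement the trimer
    purine = (centre == 0) | (centre == 2)
    cl = np.where(purine, 3 - right, left)
    cc = np.where(purine, 3 - centre, centre)
    cr = np.where(purine, 3 - left, right)
    idx = np.where(cc == 1, 0, 1) * 16 + cl * 4 + cr
    out[1:-1] = np.where(valid, idx, -1)
    return out


def census_contexts(codes: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Count genomic sites per collapsed context (length-32 vector).

    ``mask`` optionally restricts the census to a boolean subset of positions.
    Each physical site is counted exactly once (both strands collapse to the
    same pyrimidine context).
    """
    ctx = context_codes(codes)
    if mask is not None:
        ctx = np.where(mask, ctx, -1)
    valid = ctx >= 0
    return np.bincount(ctx[valid], minlength=32).astype(np.int64)
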