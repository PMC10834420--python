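"""SBS96 trinucleotide channel encoding (pyrimidine-strand convention).

Channels are ordered the standard way: six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G), within each class the 16 flanking-base
combinations sorted by 5' then 3' base (A, C, G, T). Substitutions whose
reference base is a purine are re-expressed on the reverse complement
strand before binning.
"""

from __future__ import annotations

import numpy as np

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

N_CHANNELS = 96


def channel_labels() -> list[str]:
    """The 96 channel names, e.g. ``A[C>A]A``, in canonical order."""
    labels = []
    for sub in SUBSTITUTIONS:
        for b5 in BASES:
            for b3 in BASES:
                labels.append(f"{b5}[{sub}]{b3}")
    return labels


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_index(context: str, alt: str) -> int:
    """Map a reference trinucleotide context and alt base to a channel.

    ``context`` is the reference-strand trinucleotide centred on the
    mutated base. Purine-centred contexts are reverse-complemented so the
    mutated base is always a pyrimidine (C or T).
    """
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3 or any(b not in COMPLEMENT for b in context):
        raise ValueError(f"malformed trinucleotide context: {context!r}")
    if alt not in COMPLEMENT:
        raise ValueError(f"malformed alt base: {alt!r}")
    ref = context[1]
    if ref in ("G", "A"):
        context = revcomp(context)
        alt = COMPLEMENT[alt]
        ref = context[1]
    if alt == ref:
        raise ValueError(f"alt equals ref in context {context!r}")
    sub = f"{ref}>{alt}"
    si = SUBSTITUTIONS.index(sub)
    return si * 16 + BASES.index(context[0]) * 4 + BASES.index(context[2])


def channel_to_context_alt(idx: int) -> tuple[str, str, str]:
    """Inverse of :func:`channel_index`: (context, ref, alt) on the pyrimidine strand."""
    if not 0 <= idx < N_CHANNELS:
        raise ValueError("channel index out of range")
    sub = SUBSTITUTIONS[idx // 16]
    rest = idx % 16
    b5 = BASES[rest // 4]
    b3 = BASES[rest % 4]
    ref, alt = sub.split(">")
    return f"{b5}{ref}{b3}", ref, alt


def spectrum_from_channels(channels: np.ndarray) -> np.ndarray:
    """Count vector over the 96 channels from an array of channel indices."""
    return np.bincount(np.asarray(channels, dtype=int), minlength=N_CHANNELS).astype(float)
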