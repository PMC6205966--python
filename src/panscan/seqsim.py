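"""Low-level deterministic protein-sequence simulation primitives.

These are the building blocks used both for the packaged synthetic reference
fixtures and for the pan-genome simulator: random scaffolds, hydrophobic
transmembrane blocks, and controlled divergence to a target identity.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "LIVFA"
_HYDROPHILIC = "DEKRNQSTGP"


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def rand_protein(length: int, seed_or_rng) -> str:
    """Uniform random protein over the 20 standard residues."""
    rng = _rng(seed_or_rng)
    return "".join(rng.choice(list(ALPHABET), size=length))


def tm_block(n_helices: int, seed_or_rng, helix_len: int = 21,
             loop_len: int = 15) -> str:
    """``n_helices`` hydrophobic helices separated by hydrophilic loops,
    flanked by loops on both sides."""
    rng = _rng(seed_or_rng)
    parts = ["".join(rng.choice(list(_HYDROPHILIC), size=loop_len))]
    for _ in range(n_helices):
        parts.append("".join(rng.choice(list(_HYDROPHOBIC), size=helix_len)))
        parts.append("".join(rng.choice(list(_HYDROPHILIC), size=loop_len)))
    return "".join(parts)


def dehydrophobize(seq: str, seed_or_rng, protected=(), window: int = 19,
                   cap: float = 1.5) -> str:
    """Repair a sequence so that no ``window``-residue stretch outside the
    ``protected`` regions reaches mean Kyte-Doolittle hydropathy ``cap``.

    Random scaffolds drawn uniformly over the alphabet occasionally contain
    hydrophobic windows that a sliding-window TM predictor would flag; this
    pass re-draws the most hydrophobic unprotected residue of any offending
    window from the hydrophilic set until the sequence is clean, which is
    what one expects of the soluble regions of a real protein.
    """
    from .domain_annotation import KYTE_DOOLITTLE  # local: avoid cycle at import

    rng = _rng(seed_or_rng)
    protected = set(protected)
    chars = list(seq)
    if len(chars) < window:
        return seq
    while True:
        vals = np.array([KYTE_DOOLITTLE[a] for a in chars])
        means = np.convolve(vals, np.ones(window) / window, mode="valid")
        hot = np.nonzero(means >= cap)[0]
        hot = [i for i in hot if any(
            j not in protected for j in range(i, i + window))]
        if not hot:
            return "".join(chars)
        i = int(hot[0])
        free = [j for j in range(i, i + window) if j not in protected]
        j = max(free, key=lambda j: vals[j])
        chars[j] = _HYDROPHILIC[rng.integers(len(_HYDROPHILIC))]


def mutate_to_identity(
    reference: str,
    target_identity: float,
    indel_rate: float = 0.0,
    seed=0,
    protected=(),
) -> str:
    """Derive a sequence at a controlled identity from ``reference``.

    Substitutes ``round((1 - target_identity) * L)`` uniformly chosen
    positions (each with a different residue, uniform over the other 19),
    never touching ``protected`` positions, then applies indels at the
    per-residue ``indel_rate``.  Deterministic for a given seed.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError(f"target_identity must be in (0, 1]: {target_identity}")
    rng = _rng(seed)
    L = len(reference)
    protected = set(protected)
    n_sub = round((1.0 - target_identity) * L)
    free = [i for i in range(L) if i not in protected]
    if n_sub > len(free):
        raise ValueError("not enough unprotected positions for requested identity")
    chars = list(reference)
    sub_pos = rng.choice(len(free), size=n_sub, replace=False)
    for idx in sub_pos:
        pos = free[idx]
        alternatives = [a for a in ALPHABET if a != reference[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]

    if indel_rate > 0:
        n_indel = int(rng.binomial(L, indel_rate))
        # descending positions so earlier protected coordinates stay valid
        sites = sorted(
            (int(p) for p in rng.choice(len(free), size=min(n_indel, len(free)),
                                        replace=False)),
            reverse=True,
        )
        for idx in sites:
            pos = free[idx]
            if rng.random() < 0.5:
                chars.insert(pos, ALPHABET[rng.integers(len(ALPHABET))])
            else:
                chars[pos] = ""
    return "".join(chars)
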