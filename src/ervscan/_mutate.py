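"""Nucleotide substitution machinery used by the synthetic-genome generator.

Substitutions follow a Kimura-style scheme with a transition:transversion
ratio of 2:1 (probability 2/3 that a substitution is a transition), which
makes the transition proportion P and transversion proportion Q of a mutated
pair genuinely different and the K2P correction non-trivial.

Two regimes are provided:

* ``mutate_per_site`` -- each site changes state at most once, with
  probability ``p``; the observed mismatch fraction equals ``p`` in
  expectation.  Used for outgroup divergence, which is specified as an
  observed substitution proportion.
* ``mutate_poisson`` -- each site receives ``Poisson(mu)`` substitution
  events applied sequentially, so back-mutations and multiple hits occur.
  Used for LTR neutral aging, where ``mu = age_myr * rate`` is the expected
  number of substitutions per site and the K2P estimator's multiple-hit
  correction is actually exercised.
"""

from __future__ import annotations

import numpy as np

_A, _C, _G, _T = 65, 67, 71, 84  # ASCII

# transition partner (A<->G, C<->T); identity for anything else
TRANSITION = np.arange(256, dtype=np.uint8)
TRANSITION[_A], TRANSITION[_G] = _G, _A
TRANSITION[_C], TRANSITION[_T] = _T, _C

# the two transversion choices per base
_TV1 = np.arange(256, dtype=np.uint8)
_TV2 = np.arange(256, dtype=np.uint8)
_TV1[_A], _TV2[_A] = _C, _T
_TV1[_G], _TV2[_G] = _C, _T
_TV1[_C], _TV2[_C] = _A, _G
_TV1[_T], _TV2[_T] = _A, _G

TI_FRACTION = 2.0 / 3.0


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def substitute(bases: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised single substitution of each base in ``bases``."""
    u = rng.random(bases.size)
    out = TRANSITION[bases]
    tv = u >= TI_FRACTION
    if tv.any():
        pick2 = u[tv] >= (TI_FRACTION + (1.0 - TI_FRACTION) / 2.0)
        tv_bases = np.where(pick2, _TV2[bases[tv]], _TV1[bases[tv]])
        out[tv] = tv_bases
    return out


def mutate_per_site(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy where each site is substituted once with probability p."""
    out = arr.copy()
    if p <= 0:
        return out
    idx = np.flatnonzero(rng.random(arr.size) < p)
    if idx.size:
        out[idx] = substitute(arr[idx], rng)
    return out


def mutate_poisson(arr: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy where each site receives Poisson(mu) sequential hits."""
    out = arr.copy()
    if mu <= 0:
        return out
    hits = rng.poisson(mu, arr.size)
    once = np.flatnonzero(hits == 1)
    if once.size:
        out[once] = substitute(out[once], rng)
    multi = np.flatnonzero(hits >= 2)
    for i in multi:  # rare at the divergences simulated here
        for _ in range(hits[i]):
            out[i : i + 1] = substitute(out[i : i + 1], rng)
    return out


def mutate_seq(seq: str, mu: float, rng: np.random.Generator, poisson: bool = True) -> str:
    arr = seq_to_array(seq)
    out = mutate_poisson(arr, mu, rng) if poisson else mutate_per_site(arr, mu, rng)
    return array_to_seq(out)
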