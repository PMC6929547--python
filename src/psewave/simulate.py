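"""Synthetic labelled sequence sets with class-dependent residue composition.

Each of the four structural classes gets its own residue-frequency profile
on the 20-simplex; sequences are drawn i.i.d. from their class profile.
The ``separation`` knob is calibrated in total-variation distance: profiles
are convex mixtures of the uniform composition and four seeded Dirichlet
draws, mixed so that the *minimum* pairwise total-variation distance
between class profiles equals ``separation`` (capped at what the Dirichlet
draws allow).  ``separation=0`` gives four identical uniform profiles — a
null dataset on which any composition-based classifier should sit at
chance.

Generated records are returned in a seeded random order, so that a row's
position in the dataset carries no information about its class; the
dataset-level 2-D denoising couples neighbouring rows, and an order
correlated with the labels would let that coupling leak class information
into a null experiment.

An optional first-order Markov mode adds lag correlation within sequences
so the pseudo (θ/τ) components also carry class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import AMINO_ACIDS, ProteinSequence, StructuralClass

CLASSES = tuple(StructuralClass)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    n_per_class sequences per structural class, lengths uniform in
    ``length_range`` (inclusive), class profiles separated by ``separation``
    total-variation distance.  ``markov_strength`` > 0 biases each residue
    toward (strength < 0: away from) repeating its predecessor.
    """

    n_per_class: int = 40
    length_range: tuple[int, int] = (100, 300)
    separation: float = 0.4
    seed: int = 0
    markov_strength: float = 0.0
    class_profiles: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        lo, hi = self.length_range
        if not 2 <= lo <= hi:
            raise ValueError(f"invalid length range {self.length_range}")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if not -1 < self.markov_strength < 1:
            raise ValueError("markov_strength must be in (-1, 1)")


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def make_class_profiles(spec: SyntheticSpec) -> np.ndarray:
    """Four 20-simplex residue profiles, one per class.

    Deterministic given the seed; minimum pairwise total-variation distance
    equals ``spec.separation`` where attainable.
    """
    if spec.class_profiles is not None:
        profiles = np.asarray(spec.class_profiles, dtype=float)
        if profiles.shape != (4, 20) or not np.allclose(profiles.sum(axis=1), 1.0):
            raise ValueError("class_profiles must be four 20-simplex vectors")
        return profiles
    uniform = np.full(20, 1 / 20)
    if spec.separation == 0:
        return np.tile(uniform, (4, 1))
    rng = np.random.default_rng(spec.seed)
    base = rng.dirichlet(np.ones(20), size=4)
    min_tv = min(total_variation(base[i], base[j])
                 for i in range(4) for j in range(i + 1, 4))
    mix = min(1.0, spec.separation / min_tv)
    return uniform + mix * (base - uniform)


def generate(spec: SyntheticSpec) -> list[ProteinSequence]:
    """Draw the labelled sequence set described by ``spec``.

    Residues are i.i.d. from the class profile (or first-order Markov when
    ``markov_strength`` != 0); ids encode class and index; record order is
    a seeded permutation.
    """
    profiles = make_class_profiles(spec)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    letters = np.array(list(AMINO_ACIDS))
    seqs: list[ProteinSequence] = []
    for cls, profile in zip(CLASSES, profiles):
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            if spec.markov_strength == 0.0:
                draws = rng.choice(20, size=length, p=profile)
            else:
                s = spec.markov_strength
                draws = np.empty(length, dtype=np.intp)
                draws[0] = rng.choice(20, p=profile)
                for t in range(1, length):
                    step = (1 - abs(s)) * profile.copy()
                    if s > 0:  # bias toward repeating the previous residue
                        step[draws[t - 1]] += s
                    else:  # suppress repeats
                        step[draws[t - 1]] = 0.0
                    step /= step.sum()
                    draws[t] = rng.choice(20, p=step)
            seqs.append(ProteinSequence(
                id=f"{cls.value}_{i:03d}",
                residues="".join(letters[draws]),
                label=cls,
            ))
    order = rng.permutation(len(seqs))
    return [seqs[i] for i in order]
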