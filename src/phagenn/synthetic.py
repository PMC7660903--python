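"""Synthetic protein corpora with controlled homology and class signal.

The generator emulates exactly the statistical structure the split and
the classifier assume about real corpora: each class is a union of
homologous families (members of one family are close in identity,
ancestors of different families are distant), and classes differ in
residue composition, which is the signal the composition-based
features can detect. The background class ("others") draws from the
untilted background profile, so it carries no class signal of its own.

Families are built by mutating a family ancestor: each member
substitutes a fraction of sites (drawn from the class profile,
excluding the original residue) plus a low rate of single-residue
indels, so alignment identity tracks substitution identity closely.
``within_family_identity`` is the expected *pairwise* identity between
two members of a family; each member therefore diverges from the
ancestor by half the complementary rate. Ancestors are rejection-
sampled until they are at most ``between_family_identity_max``
identical to every previously accepted ancestor, across all classes —
this gap (families near 0.9 identity inside, below 0.25 between, with
the clustering threshold at 0.40 in between) is what makes the
homology split's no-leakage property exactly verifiable.

Class composition profiles are the background profile tilted by a
class-specific log-normal factor: profile_c ∝ background ·
exp(strength · g_c) with g_c a fixed standard-normal draw per class.
At strength 0 every class shares the background profile (the negative
control); the default strength of 1.0 makes residue preferences differ
by factors of roughly e^{±1} between classes, a strong but not
degenerate compositional signal (the positive control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from phagenn.homology_split import pairwise_identity
from phagenn.seqio import CANONICAL_AA, DEFAULT_CLASS_NAMES, ProteinRecord

logger = logging.getLogger(__name__)

_AA = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class SyntheticConfig:
    n_classes: int = 11
    #: one homologous family per cross-validation set by default, so
    #: every set receives members of every class
    families_per_class: int = 11
    members_per_family: int = 4
    length_range: tuple[int, int] = (80, 600)
    within_family_identity: float = 0.90
    between_family_identity_max: float = 0.25
    class_bias_strength: float = 1.0
    indel_rate: float = 0.01
    rng_seed: int = 0
    class_names: tuple[str, ...] | None = None
    #: attempts to draw a sufficiently novel family ancestor
    rejection_cap: int = 200

    def __post_init__(self) -> None:
        if self.length_range[0] < 2:
            raise ValueError("sequences must have length >= 2")
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0, 1]")
        if self.class_bias_strength < 0:
            raise ValueError("class_bias_strength must be >= 0")

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            if len(self.class_names) != self.n_classes:
                raise ValueError("class_names length must equal n_classes")
            return self.class_names
        if self.n_classes == len(DEFAULT_CLASS_NAMES):
            return DEFAULT_CLASS_NAMES
        # generic names, last one the background class
        return tuple(f"class_{i + 1}" for i in range(self.n_classes - 1)) + ("others",)


def _background_profile() -> np.ndarray:
    """Mildly non-uniform residue background (common residues like
    A/G/L slightly enriched, W/C rare), fixed across seeds."""
    weights = np.array([
        8.3,  # A
        1.4,  # C
        5.5,  # D
        6.8,  # E
        3.9,  # F
        7.1,  # G
        2.3,  # H
        6.0,  # I
        5.8,  # K
        9.7,  # L
        2.4,  # M
        4.1,  # N
        4.7,  # P
        3.9,  # Q
        5.5,  # R
        6.6,  # S
        5.4,  # T
        6.9,  # V
        1.1,  # W
        2.9,  # Y
    ])
    return weights / weights.sum()


def _class_profiles(config: SyntheticConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Background profile tilted per class; the background class (the
    last one) always keeps the untilted profile.

    Tilts are redrawn until the profile's concentration (sum of squared
    frequencies, the per-column match probability of unrelated
    sequences) stays within 2.2x the background's — a bias shifts
    residue preferences without collapsing the profile onto a few
    residues, which would make unrelated sequences of that class look
    spuriously homologous.
    """
    base = _background_profile()
    concentration_cap = 2.2 * float((base ** 2).sum())
    profiles = []
    for ci in range(config.n_classes):
        if ci == config.n_classes - 1:
            # the tilt draw is consumed regardless, to keep per-class
            # profiles independent of how many classes precede them
            rng.standard_normal(len(base))
            profiles.append(base)
            continue
        while True:
            tilt = rng.standard_normal(len(base))
            p = base * np.exp(config.class_bias_strength * tilt)
            p = p / p.sum()
            if config.class_bias_strength == 0 or (p ** 2).sum() <= concentration_cap:
                break
        profiles.append(p)
    return profiles


def _draw_sequence(length: int, profile: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(_AA[rng.choice(len(_AA), size=length, p=profile)])


def _mutate(ancestor: str, profile: np.ndarray, sub_rate: float,
            indel_rate: float, rng: np.random.Generator) -> str:
    """Substitute an exact fraction of sites (positions random, counts
    deterministic, so divergence is controlled rather than binomial)
    plus a low rate of single-residue indels."""
    seq = np.array(list(ancestor))
    n_sub = round(len(seq) * sub_rate)
    if n_sub:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        for p in pos:
            orig_i = CANONICAL_AA.index(seq[p])
            w = profile.copy()
            w[orig_i] = 0.0  # substitutions always change the residue
            w /= w.sum()
            seq[p] = _AA[rng.choice(len(_AA), p=w)]
    out = list(seq)
    n_indel = round(len(out) * indel_rate)
    for _ in range(n_indel):
        p = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > 2:
            del out[p]
        else:
            out.insert(p, str(_AA[rng.choice(len(_AA), p=profile)]))
    return "".join(out)


def generate_corpus(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[dict[str, list[ProteinRecord]], dict[str, str]]:
    """Generate the labeled corpus.

    Returns (class→records, id→class truth). Deterministic for a fixed
    seed. Raises if a family ancestor cannot be drawn within the
    rejection cap (too many families for the requested divergence).
    """
    rng = np.random.default_rng(config.rng_seed)
    names = config.resolved_class_names()
    profiles = _class_profiles(config, rng)
    member_sub_rate = (1.0 - config.within_family_identity) / 2.0

    corpora: dict[str, list[ProteinRecord]] = {}
    truth: dict[str, str] = {}
    accepted_ancestors: list[str] = []
    for ci, cls in enumerate(names):
        profile = profiles[ci]
        records: list[ProteinRecord] = []
        for fi in range(config.families_per_class):
            ancestor = None
            for _attempt in range(config.rejection_cap):
                length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
                cand = _draw_sequence(length, profile, rng)
                if all(
                    pairwise_identity(cand, prev) <= config.between_family_identity_max
                    for prev in accepted_ancestors
                ):
                    ancestor = cand
                    break
            if ancestor is None:
                raise RuntimeError(
                    f"could not draw a family ancestor for class {cls!r} within "
                    f"{config.rejection_cap} attempts; use longer sequences or "
                    f"fewer families"
                )
            accepted_ancestors.append(ancestor)
            for mi in range(config.members_per_family):
                seq = _mutate(ancestor, profile, member_sub_rate, config.indel_rate, rng)
                rec_id = f"c{ci + 1:02d}_f{fi + 1}_m{mi + 1}"
                records.append(ProteinRecord(
                    id=rec_id, sequence=seq,
                    description=f"synthetic {cls} family {fi + 1} member {mi + 1}",
                    label=cls,
                ))
                truth[rec_id] = cls
        corpora[cls] = records
    return corpora, truth


def generate_worked_fixture() -> tuple[dict[str, list[ProteinRecord]], dict[str, str]]:
    """A tiny deterministic corpus (36 sequences, 3 classes × 3
    families × 4 members, short sequences) used for frozen-expectation
    tests: its clusters and split sets are precomputed once with the
    brute-force all-pairs oracle and asserted against."""
    config = SyntheticConfig(
        n_classes=3,
        families_per_class=3,
        members_per_family=4,
        length_range=(60, 100),
        rng_seed=20_200_515,
    )
    return generate_corpus(config)
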