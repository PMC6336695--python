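"""Shared fixtures: hand-built pedigrees, random-pedigree machinery, and a
from-scratch literal likelihood oracle used to validate both engine paths."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famseg.linkage import DiseaseModel, MarkerModel
from famseg.pedigree import Affection, Pedigree, PedigreeMember, Sex

settings.register_profile(
    "famseg",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("famseg")


def member(
    fid: str,
    iid: str,
    father: str | None = None,
    mother: str | None = None,
    sex: Sex = Sex.UNKNOWN,
    affection: Affection = Affection.UNKNOWN,
    proband: bool = False,
) -> PedigreeMember:
    return PedigreeMember(fid, iid, father, mother, sex, affection, proband)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        "T",
        [
            member("T", "dad", sex=Sex.MALE, affection=Affection.UNAFFECTED),
            member("T", "mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
            member("T", "kid", "dad", "mom", affection=Affection.AFFECTED),
        ],
    )


@pytest.fixture
def three_gen() -> Pedigree:
    """Three generations, 7 members, one married-in spouse per generation:
    founders gf, gm, mom, wife -> 4 founders by hand."""
    return Pedigree(
        "G",
        [
            member("G", "gf", sex=Sex.MALE, affection=Affection.AFFECTED),
            member("G", "gm", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
            member("G", "dad", "gf", "gm", Sex.MALE, Affection.AFFECTED),
            member("G", "mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
            member("G", "son", "dad", "mom", Sex.MALE, Affection.AFFECTED),
            member("G", "wife", sex=Sex.FEMALE),
            member("G", "grandkid", "son", "wife", Sex.FEMALE),
        ],
    )


@pytest.fixture
def cousin_loop() -> Pedigree:
    """First-cousin marriage: the canonical loop pedigree."""
    return Pedigree(
        "L",
        [
            member("L", "gf", sex=Sex.MALE),
            member("L", "gm", sex=Sex.FEMALE),
            member("L", "a", "gf", "gm", Sex.MALE),
            member("L", "b", "gf", "gm", Sex.FEMALE),
            member("L", "spa", sex=Sex.FEMALE),
            member("L", "spb", sex=Sex.MALE),
            member("L", "c", "a", "spa", Sex.MALE),
            member("L", "d", "spb", "b", Sex.FEMALE),
            member("L", "e", "c", "d"),
        ],
    )


def phase_known_family(k: int, family_id: str = "K"):
    """A fully informative dominant family: the transmitting parent's phase
    and heterozygosity are pinned by a typed unaffected grandmother (full
    penetrance) and an untyped unknown-phenotype grandfather, so each of the
    k affected het children is one scorable meiosis."""
    members = [
        member(family_id, "ggf", sex=Sex.MALE),
        member(family_id, "ggm", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
        member(family_id, "dad", "ggf", "ggm", Sex.MALE, Affection.AFFECTED),
        member(family_id, "mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
    ] + [
        member(family_id, f"c{i}", "dad", "mom", affection=Affection.AFFECTED)
        for i in range(k)
    ]
    genotypes = {"ggm": 0, "dad": 1, "mom": 0, **{f"c{i}": 1 for i in range(k)}}
    return Pedigree(family_id, members), genotypes


def random_pedigree(rng: np.random.Generator, max_members: int = 7) -> Pedigree:
    """Small random loop-free pedigree with random phenotypes (for oracle
    comparisons): a nuclear family or a three-generation chain."""

    def aff():
        return [Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN][
            int(rng.integers(3))
        ]

    fid = "R"
    if rng.random() < 0.5:
        k = int(rng.integers(1, max_members - 1))
        members = [
            member(fid, "f", sex=Sex.MALE, affection=aff()),
            member(fid, "m", sex=Sex.FEMALE, affection=aff()),
        ] + [
            member(fid, f"c{i}", "f", "m", affection=aff()) for i in range(k)
        ]
    else:
        k = int(rng.integers(1, max_members - 4))
        members = [
            member(fid, "gf", sex=Sex.MALE, affection=aff()),
            member(fid, "gm", sex=Sex.FEMALE, affection=aff()),
            member(fid, "p", "gf", "gm", Sex.MALE, affection=aff()),
            member(fid, "s", sex=Sex.FEMALE, affection=aff()),
        ] + [
            member(fid, f"c{i}", "p", "s", affection=aff()) for i in range(k)
        ]
    return Pedigree(fid, members)


def random_genotypes(rng: np.random.Generator, ped: Pedigree) -> dict[str, int]:
    out = {}
    for iid in ped.member_ids:
        g = int(rng.integers(-1, 3))
        if g >= 0:
            out[iid] = g
    return out


# -- literal oracle ----------------------------------------------------------
# A from-first-principles implementation sharing no code with the package:
# its own haplotype encoding, transmission table, penetrances and priors.


def literal_log10_likelihood(
    ped: Pedigree,
    genotypes: dict[str, int],
    disease: DiseaseModel,
    marker: MarkerModel,
    theta: float,
) -> float:
    haps = [(d, a) for d in (0, 1) for a in (0, 1)]
    states = list(itertools.product(haps, haps))  # ordered diplotypes

    def gametes(state):
        (hp, hm) = state
        probs: dict[tuple[int, int], float] = {}
        for g, p in [
            (hp, (1 - theta) / 2),
            (hm, (1 - theta) / 2),
            ((hp[0], hm[1]), theta / 2),
            ((hm[0], hp[1]), theta / 2),
        ]:
            probs[g] = probs.get(g, 0.0) + p
        return probs

    q, p = disease.disease_allele_freq, marker.alt_allele_freq
    pen = [disease.phenocopy_dd, disease.penetrance_Dd, disease.penetrance_DD]

    def hap_prior(h):
        return (q if h[0] else 1 - q) * (p if h[1] else 1 - p)

    def weight(m: PedigreeMember, state) -> float:
        (hp, hm) = state
        w = 1.0
        if m.is_founder:
            w *= hap_prior(hp) * hap_prior(hm)
        n_d = hp[0] + hm[0]
        if m.affection is Affection.AFFECTED:
            w *= pen[n_d]
        elif m.affection is Affection.UNAFFECTED:
            w *= 1 - pen[n_d]
        obs = genotypes.get(m.individual_id)
        if obs is not None and hp[1] + hm[1] != obs:
            w = 0.0
        return w

    members = ped.members
    total = 0.0
    for assign in itertools.product(range(16), repeat=len(members)):
        chosen = {
            m.individual_id: states[s] for m, s in zip(members, assign)
        }
        prob = 1.0
        for m in members:
            prob *= weight(m, chosen[m.individual_id])
            if prob == 0.0:
                break
            if not m.is_founder:
                st = chosen[m.individual_id]
                prob *= gametes(chosen[m.father_id]).get(st[0], 0.0)
                prob *= gametes(chosen[m.mother_id]).get(st[1], 0.0)
                if prob == 0.0:
                    break
        total += prob
    return math.log10(total) if total > 0.0 else -math.inf
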