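"""Seeded synthetic repertoire generator.

Emulates post-error-correction clone tables from sorted mouse T-cell
samples: per-clone V gene, CDR3 nucleotide and amino-acid sequence, and a
detection count with appreciable singleton/doubleton mass.  The controlling
parameter is ``apex_cys_prob``, the probability that a clone carries a
forced Cys inside the apex +/-2 window; lineage defaults follow the
wild-type enrichment pattern in which CD8aa IEL and their thymic
precursors are Cys-enriched (roughly 6-10%) while conventional T cells are
depleted.  Attenuated-TCR-signaling or MHC-deficient genotypes flatten all
lineages to the preselection probability.

Residues outside the forced positions are drawn i.i.d. from a background
table with Cys down-weighted to 1%, so the measured cysteine index tracks
``apex_cys_prob`` plus a small, measurable background leakage.  Nucleotide
sequences are seeded codon back-translations, letting distinct clones
(nucleotide level) encode one clonotype (amino-acid level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cysteine_index import APEX_WINDOW, middle_position
from .repertoire_core import (
    AMINO_ACIDS,
    CODON_TABLE,
    Chain,
    CloneRecord,
    Lineage,
    RepertoireSample,
    chain_of_v_gene,
)

CDR3_LENGTHS = tuple(range(4, 21))

#: Background residue frequencies: uniform with Cys down-weighted to 1%.
BACKGROUND_CYS_FREQ = 0.01

DEFAULT_BETA_V_GENES = (
    "TRBV1", "TRBV2", "TRBV5", "TRBV13-1", "TRBV16", "TRBV19", "TRBV29", "TRBV31",
)
DEFAULT_ALPHA_V_GENES = (
    "TRAV6", "TRAV7", "TRAV9", "TRAV12", "TRAV14", "TRAV16", "TRAV19", "TRAV21",
)

GENOTYPE_EFFECTS = ("wild_type", "signaling_attenuated", "mhc_deficient")


class ConfigError(ValueError):
    """Profile or study configuration is internally inconsistent."""


def _default_length_distribution() -> tuple[float, ...]:
    # Unimodal around 11-12 aa, the typical mouse CDR3beta length.
    pmf = stats.binom.pmf(np.arange(len(CDR3_LENGTHS)), len(CDR3_LENGTHS) - 1, 0.45)
    return tuple(pmf / pmf.sum())


def _uniform(n: int) -> tuple[float, ...]:
    return tuple(np.full(n, 1.0 / n))


@dataclass(frozen=True)
class LineageProfile:
    """Generative parameters for one lineage's samples."""

    lineage: Lineage = Lineage.other
    n_clones: int = 5000
    apex_cys_prob: float = 0.01
    cdr3_length_distribution: tuple[float, ...] = field(
        default_factory=_default_length_distribution
    )
    v_gene_usage: tuple[float, ...] | None = None
    v_genes: tuple[str, ...] = DEFAULT_BETA_V_GENES
    chain: Chain = Chain.beta
    trbv1_germline_cys: bool = True
    singleton_fraction: float = 0.1
    doubleton_fraction: float = 0.1
    count_geometric_p: float = 0.35
    background_cys_freq: float = BACKGROUND_CYS_FREQ

    def __post_init__(self) -> None:
        if not 0.0 <= self.apex_cys_prob <= 1.0:
            raise ConfigError("apex_cys_prob must lie in [0, 1]")
        if self.singleton_fraction + self.doubleton_fraction > 1.0:
            raise ConfigError("singleton + doubleton mass exceeds 1")
        if abs(sum(self.cdr3_length_distribution) - 1.0) > 1e-12:
            raise ConfigError("cdr3_length_distribution must sum to 1")
        if len(self.cdr3_length_distribution) != len(CDR3_LENGTHS):
            raise ConfigError(
                f"cdr3_length_distribution needs {len(CDR3_LENGTHS)} entries"
            )
        if self.v_gene_usage is not None:
            if len(self.v_gene_usage) != len(self.v_genes):
                raise ConfigError("v_gene_usage length mismatch")
            if abs(sum(self.v_gene_usage) - 1.0) > 1e-12:
                raise ConfigError("v_gene_usage must sum to 1")

    @property
    def usage(self) -> tuple[float, ...]:
        return self.v_gene_usage or _uniform(len(self.v_genes))


def _background_probs(cys_freq: float) -> np.ndarray:
    probs = np.full(len(AMINO_ACIDS), (1.0 - cys_freq) / (len(AMINO_ACIDS) - 1))
    probs[AMINO_ACIDS.index("C")] = cys_freq
    return probs


def _back_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        CODON_TABLE[res][rng.integers(len(CODON_TABLE[res]))] for res in aa
    )


def generate_sample(
    profile: LineageProfile,
    seed: int,
    sample_id: str | None = None,
    genotype: str = "wild_type",
) -> RepertoireSample:
    """Draw one repertoire sample; fully determined by (profile, seed)."""
    rng = np.random.default_rng(seed)
    bg = _background_probs(profile.background_cys_freq)
    aa_array = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    clones: dict[tuple[str, str], CloneRecord] = {}
    attempts = 0
    while len(clones) < profile.n_clones:
        attempts += 1
        if attempts > 50 * profile.n_clones:
            raise ConfigError("cannot draw enough unique clones; panel too small")
        length = int(
            rng.choice(len(CDR3_LENGTHS), p=profile.cdr3_length_distribution)
        ) + CDR3_LENGTHS[0]
        v_gene = profile.v_genes[rng.choice(len(profile.v_genes), p=profile.usage)]
        residues = list(aa_array[rng.choice(len(aa_array), size=length, p=bg)])
        if v_gene.upper() == "TRBV1" and profile.trbv1_germline_cys and length >= 2:
            residues[1] = "C"
        if rng.random() < profile.apex_cys_prob:
            apex = middle_position(length)
            lo = max(1, apex - APEX_WINDOW)
            hi = min(length, apex + APEX_WINDOW)
            residues[int(rng.integers(lo, hi + 1)) - 1] = "C"
        cdr3 = "".join(residues)
        junction_aa = "C" + cdr3 + "F"
        junction_nt = _back_translate(junction_aa, rng)

        u = rng.random()
        if u < profile.singleton_fraction:
            count = 1
        elif u < profile.singleton_fraction + profile.doubleton_fraction:
            count = 2
        else:
            count = 3 + int(rng.geometric(profile.count_geometric_p)) - 1

        key = (v_gene, junction_nt)
        if key in clones:
            continue
        clones[key] = CloneRecord(
            v_gene=v_gene,
            chain=chain_of_v_gene(v_gene),
            cdr3_nt=junction_nt,
            junction_aa=junction_aa,
            cdr3_aa=cdr3,
            detection_count=count,
            productive=True,
        )
    return RepertoireSample(
        sample_id=sample_id or f"{profile.lineage.value}-{seed}",
        clones=list(clones.values()),
        chain=profile.chain,
        lineage=profile.lineage,
        genotype=genotype,
    )


STUDY_LINEAGES = (
    Lineage.CD4_Tconv,
    Lineage.CD8_Tconv,
    Lineage.preselection,
    Lineage.TypeA_IELp_CD8aaIEL,
)

#: Wild-type apex-Cys probabilities: conventional T cells depleted,
#: preselection intermediate, CD8aa IEL lineage enriched (6-10% anchor).
DEFAULT_APEX_CYS_PROBS: dict[Lineage, float] = {
    Lineage.CD4_Tconv: 0.01,
    Lineage.CD8_Tconv: 0.01,
    Lineage.preselection: 0.03,
    Lineage.TypeA_IELp_CD8aaIEL: 0.08,
}


@dataclass(frozen=True)
class StudyConfig:
    """Design of a multi-lineage, multi-genotype synthetic study."""

    profiles: dict[Lineage, LineageProfile] = field(default_factory=dict)
    genotype_effects: tuple[str, ...] = ("wild_type",)
    n_mice_per_group: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.genotype_effects:
            if g not in GENOTYPE_EFFECTS:
                raise ConfigError(f"unknown genotype effect {g!r}")
        if self.n_mice_per_group < 1:
            raise ConfigError("n_mice_per_group must be >= 1")

    def profile_for(self, lineage: Lineage, genotype: str) -> LineageProfile:
        base = self.profiles.get(lineage) or LineageProfile(
            lineage=lineage, apex_cys_prob=DEFAULT_APEX_CYS_PROBS[lineage]
        )
        base = replace(base, lineage=lineage)
        if genotype != "wild_type":
            # Attenuated signaling / MHC deficiency abolish agonist selection:
            # every lineage keeps the preselection Cys frequency.
            presel = self.profiles.get(Lineage.preselection) or LineageProfile(
                lineage=Lineage.preselection,
                apex_cys_prob=DEFAULT_APEX_CYS_PROBS[Lineage.preselection],
            )
            base = replace(base, apex_cys_prob=presel.apex_cys_prob)
        return base


def generate_study(
    config: StudyConfig,
) -> tuple[list[RepertoireSample], pd.DataFrame]:
    """Generate all samples of a study plus a manifest of true parameters.

    One sample per (genotype, lineage, mouse); per-sample seeds are derived
    deterministically from ``config.seed`` so the whole study is
    reproducible from the config alone.
    """
    root = np.random.default_rng(config.seed)
    samples: list[RepertoireSample] = []
    rows: list[dict] = []
    for genotype in config.genotype_effects:
        for lineage in STUDY_LINEAGES:
            profile = config.profile_for(lineage, genotype)
            for mouse in range(config.n_mice_per_group):
                sub_seed = int(root.integers(0, 2**31 - 1))
                sid = f"{genotype}_{lineage.value}_m{mouse + 1}"
                samples.append(
                    generate_sample(profile, sub_seed, sample_id=sid, genotype=genotype)
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "lineage": lineage.value,
                        "mouse": mouse + 1,
                        "n_clones": profile.n_clones,
                        "apex_cys_prob": profile.apex_cys_prob,
                        "seed": sub_seed,
                    }
                )
    return samples, pd.DataFrame(rows)


def study_config_from_probs(
    probs: dict[Lineage, float] | None = None,
    n_clones: int = 5000,
    genotype_effects: Sequence[str] = ("wild_type",),
    n_mice_per_group: int = 4,
    seed: int = 0,
) -> StudyConfig:
    """Convenience constructor from per-lineage apex-Cys probabilities."""
    probs = dict(DEFAULT_APEX_CYS_PROBS if probs is None else probs)
    profiles = {
        lin: LineageProfile(lineage=lin, n_clones=n_clones, apex_cys_prob=p)
        for lin, p in probs.items()
    }
    return StudyConfig(
        profiles=profiles,
        genotype_effects=tuple(genotype_effects),
        n_mice_per_group=n_mice_per_group,
        seed=seed,
    )
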