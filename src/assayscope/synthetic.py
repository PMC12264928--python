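"""Synthetic assay corpora and bioactivity tables with known ground truth.

The generator emulates the structure of curated ChEMBL/Papyrus exports:

* assay descriptions are token templates drawn from archetype-specific
  keyword pools (emulating assay categories such as radioligand
  displacement vs. cAMP accumulation) mixed with shared filler vocabulary;
* categorical metadata is sampled from archetype-conditional distributions;
* pChEMBL values follow an additive model
  ``pchembl(c, t, a) = mu_t + beta_c + delta_archetype(a) + eps`` with
  ``mu_t ~ N(6.5, 0.5^2)`` (per-target affinity level), ``beta_c ~ N(0, 1)``
  (per-compound potency), ``delta`` drawn once per archetype
  ``~ N(0, offset_sd^2)`` (systematic assay-category shift) and Gaussian
  noise ``eps ~ N(0, noise_sd^2)``; each compound-target pair is measured in
  ``Poisson(replicate_rate) + 1`` assays with uniformly sampled archetypes.

SMILES come from a packaged combinatorial drug-like library
(``data/druglike.smi``, synthetic structures validated with RDKit), so real
fingerprint code is exercised without any download.  Protein sequences are
mutated copies of a random consensus — equal length, hence pre-aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import AssayCorpus, AssayRecord, BioactivityPoint, BioactivityTable
from .errors import ConfigError

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ArchetypeSpec:
    """One assay archetype: its private keywords, shared filler, metadata
    distributions and (recorded) activity offset."""

    name: str
    keyword_pool: tuple[str, ...]
    filler_pool: tuple[str, ...]
    metadata_distribution: Mapping[str, Mapping[str, float]]
    activity_offset: float = 0.0

    def __post_init__(self):
        for prop, dist in self.metadata_distribution.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{self.name}: probabilities for {prop!r} sum to {total}")


_FILLER = (
    "measured", "membrane", "receptor", "protein", "response", "buffer",
    "concentration", "incubation", "minutes", "expressed", "recombinant",
    "transfected", "determined", "using", "assay", "signal", "analysis",
    "dose", "control", "wildtype", "room", "temperature", "plate", "reader",
    "value",
)


def default_archetypes() -> list[ArchetypeSpec]:
    """Five archetypes mirroring common assay categories."""
    def meta(assay_type, bao, standard):
        return {
            "assay_type": assay_type,
            "bao_format": bao,
            "standard_type": standard,
        }

    return [
        ArchetypeSpec(
            "radioligand_displacement",
            ("displacement", "radioligand", "3h", "125i", "scintillation",
             "counting", "dpcpx", "binding", "filtration", "specific",
             "nonspecific", "competition"),
            _FILLER,
            meta({"B": 0.9, "F": 0.1}, {"BAO_0000357": 0.8, "BAO_0000219": 0.2},
                 {"Ki": 0.7, "IC50": 0.3})),
        ArchetypeSpec(
            "camp_accumulation",
            ("camp", "forskolin", "accumulation", "stimulated", "agonist",
             "cyclase", "adenylyl", "gs", "glosensor", "lance", "htrf",
             "epac"),
            _FILLER,
            meta({"F": 0.9, "B": 0.1}, {"BAO_0000219": 0.7, "BAO_0000357": 0.3},
                 {"EC50": 0.6, "IC50": 0.4})),
        ArchetypeSpec(
            "calcium_flux",
            ("calcium", "flipr", "fluo", "mobilization", "flux", "dye",
             "fluorescence", "intracellular", "loading", "kinetic",
             "ionomycin", "transient"),
            _FILLER,
            meta({"F": 0.95, "B": 0.05}, {"BAO_0000219": 0.9, "BAO_0000019": 0.1},
                 {"EC50": 0.5, "IC50": 0.5})),
        ArchetypeSpec(
            "enzyme_inhibition",
            ("kinase", "phosphorylation", "atp", "substrate", "peptide",
             "enzymatic", "catalytic", "autophosphorylation", "km",
             "radiometric", "luminescence", "adp"),
            _FILLER,
            meta({"B": 0.6, "F": 0.4}, {"BAO_0000357": 0.6, "BAO_0000019": 0.4},
                 {"IC50": 0.8, "Ki": 0.2})),
        ArchetypeSpec(
            "cell_proliferation",
            ("proliferation", "viability", "mtt", "growth", "cytotoxicity",
             "survival", "colony", "tumor", "xtt", "resazurin", "culture",
             "antiproliferative"),
            _FILLER,
            meta({"F": 1.0}, {"BAO_0000219": 0.8, "BAO_0000019": 0.2},
                 {"IC50": 0.6, "GI50": 0.4})),
    ]


def _check_disjoint(archetypes: Sequence[ArchetypeSpec]) -> None:
    seen: dict[str, str] = {}
    for arch in archetypes:
        for kw in arch.keyword_pool:
            if kw in seen and seen[kw] != arch.name:
                raise ConfigError(f"keyword {kw!r} shared by archetypes "
                                  f"{seen[kw]!r} and {arch.name!r}")
            seen[kw] = arch.name


@dataclass
class SyntheticCorpus:
    """Generated assay corpus with a true archetype label per record."""

    corpus: AssayCorpus
    true_archetype: list[str]

    def __len__(self) -> int:
        return len(self.corpus)


def _sample_categorical(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    cats = sorted(dist)
    probs = np.array([dist[c] for c in cats])
    return cats[int(rng.choice(len(cats), p=probs / probs.sum()))]


def generate_assay_corpus(
    archetypes: Sequence[ArchetypeSpec] | None = None,
    n_per_archetype: int = 200,
    seed: int = 0,
    keyword_fraction: float = 0.6,
) -> SyntheticCorpus:
    """Generate ``n_per_archetype`` assay records per archetype.

    Each description has 8–20 tokens, ~60% drawn from the archetype's
    keyword pool and ~40% from the shared filler, joined with spaces.
    Deterministic given the seed.
    """
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    if len(archetypes) < 2 or n_per_archetype < 2:
        raise ConfigError("need >= 2 archetypes and >= 2 records per archetype")
    _check_disjoint(archetypes)
    rng = np.random.default_rng(seed)
    records: list[AssayRecord] = []
    labels: list[str] = []
    i = 0
    for arch in archetypes:
        for _ in range(n_per_archetype):
            n_tokens = int(rng.integers(8, 21))
            tokens = []
            for _ in range(n_tokens):
                pool = arch.keyword_pool if rng.random() < keyword_fraction else arch.filler_pool
                tokens.append(pool[int(rng.integers(len(pool)))])
            meta = {prop: _sample_categorical(rng, dist)
                    for prop, dist in arch.metadata_distribution.items()}
            records.append(AssayRecord(
                assay_id=f"SYN-A{i:06d}",
                description=" ".join(tokens),
                assay_type=meta.get("assay_type", "B"),
                standard_type=meta.get("standard_type", "IC50"),
                bao_format=meta.get("bao_format", "BAO_0000357"),
                tax_id="9606", confidence_score="9", relationship_type="D",
                src_id="1", curated_by="Autocuration", pref_name=arch.name))
            labels.append(arch.name)
            i += 1
    corpus = AssayCorpus(records)
    corpus.log("generate_assay_corpus", n_per_archetype=n_per_archetype,
               n_archetypes=len(archetypes), seed=seed)
    return SyntheticCorpus(corpus=corpus, true_archetype=labels)


def packaged_smiles() -> list[str]:
    """The packaged drug-like SMILES library (synthetic combinatorial
    structures, all RDKit-valid)."""
    text = resources.files("assayscope").joinpath("data/druglike.smi").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class SyntheticBioactivity:
    """Generated bioactivity table plus the full generative record."""

    table: BioactivityTable
    assays: SyntheticCorpus
    truth: dict = field(default_factory=dict)
    alignment: dict[str, str] = field(default_factory=dict)


def _mutate_consensus(rng: np.random.Generator, consensus: str, n_mut: int) -> str:
    seq = list(consensus)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        seq[pos] = _AMINO_ACIDS[int(rng.integers(20))]
    return "".join(seq)


def generate_bioactivity(
    n_targets: int = 10,
    n_compounds_per_target: int = 50,
    archetypes: Sequence[ArchetypeSpec] | None = None,
    replicate_rate: float = 2.0,
    offset_sd: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
    n_assays_per_archetype: int = 25,
    seq_length: int = 60,
) -> SyntheticBioactivity:
    """Generate a bioactivity table with additive target/compound/archetype
    effects (see module docstring for the generative model).

    Every measurement links to a generated assay record of its archetype, so
    the table joins cleanly to the returned assay corpus.  Protein sequences
    are equal-length mutants of a consensus and are returned as a
    ready-to-use alignment.
    """
    if n_targets <= 0 or n_compounds_per_target <= 0 or noise_sd < 0:
        raise ConfigError("sizes must be positive and noise_sd >= 0")
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    rng = np.random.default_rng(seed)

    assays = generate_assay_corpus(archetypes, n_assays_per_archetype,
                                   seed=int(rng.integers(2**31 - 1)))
    by_arch: dict[str, list[str]] = {}
    for rec, arch in zip(assays.corpus.records, assays.true_archetype):
        by_arch.setdefault(arch, []).append(rec.assay_id)

    smiles_pool = packaged_smiles()
    mu = rng.normal(6.5, 0.5, size=n_targets)
    delta = {arch.name: float(rng.normal(0.0, offset_sd)) for arch in archetypes}
    arch_names = [a.name for a in archetypes]

    consensus = "".join(_AMINO_ACIDS[int(rng.integers(20))] for _ in range(seq_length))
    alignment = {f"SYNP{t:03d}": _mutate_consensus(rng, consensus, max(1, seq_length // 8))
                 for t in range(n_targets)}

    beta: dict[int, float] = {}
    mw_cache: dict[str, float] = {}
    try:
        from rdkit.Chem import Descriptors, MolFromSmiles
        have_rdkit = True
    except ImportError:  # pragma: no cover
        have_rdkit = False

    points: list[BioactivityPoint] = []
    for t in range(n_targets):
        accession = f"SYNP{t:03d}"
        comp_idx = rng.choice(len(smiles_pool), size=n_compounds_per_target, replace=False)
        for c in comp_idx:
            c = int(c)
            if c not in beta:
                beta[c] = float(rng.normal(0.0, 1.0))
            smi = smiles_pool[c]
            if smi not in mw_cache:
                mw_cache[smi] = (float(Descriptors.MolWt(MolFromSmiles(smi)))
                                 if have_rdkit else 300.0)
            n_meas = int(rng.poisson(replicate_rate)) + 1
            for _ in range(n_meas):
                arch = arch_names[int(rng.integers(len(arch_names)))]
                assay_id = by_arch[arch][int(rng.integers(len(by_arch[arch])))]
                value = mu[t] + beta[c] + delta[arch] + rng.normal(0.0, noise_sd)
                points.append(BioactivityPoint(
                    compound_id=f"C{c:05d}", smiles=smi, target_accession=accession,
                    pchembl=float(value), assay_id=assay_id,
                    standard_type="IC50", quality_flag="high", censored=False,
                    mw=mw_cache[smi]))
    table = BioactivityTable(points)
    table.log("generate_bioactivity", n_targets=n_targets,
              n_compounds_per_target=n_compounds_per_target,
              replicate_rate=replicate_rate, offset_sd=offset_sd,
              noise_sd=noise_sd, seed=seed)
    truth = {
        "mu": {f"SYNP{t:03d}": float(mu[t]) for t in range(n_targets)},
        "beta": {f"C{c:05d}": b for c, b in beta.items()},
        "delta": delta,
        "noise_sd": noise_sd,
        "offset_sd": offset_sd,
        "assay_archetype": dict(zip(assays.corpus.assay_ids, assays.true_archetype)),
    }
    return SyntheticBioactivity(table=table, assays=assays, truth=truth,
                                alignment=alignment)


def ground_truth_report(obj: SyntheticCorpus | SyntheticBioactivity) -> dict:
    """Machine-readable truth of a generated object (JSON-serializable)."""
    if isinstance(obj, SyntheticCorpus):
        return {"kind": "assay_corpus",
                "true_archetype": dict(zip(obj.corpus.assay_ids, obj.true_archetype))}
    if isinstance(obj, SyntheticBioactivity):
        return {"kind": "bioactivity", **obj.truth}
    raise ConfigError(f"not a synthetic object: {type(obj)!r}")


def write_ground_truth(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth_report(obj), indent=2))


def write_alignment_fasta(alignment: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in alignment.items():
            fh.write(f">{acc}\n{seq}\n")
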