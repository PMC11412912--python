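"""Synthetic multiplexed-TMT data with known ground truth.

The generator emulates the statistical structure of reporter-ion
quantification from isobaric-label (TMT) experiments: per-channel
peptide intensities with multiplicative log-normal noise, group-wise
protein fold changes, and peptide-subset ("isoform") effects that model
exon-level silencing — e.g. a genotype in which a block of exons has
been deleted so that the peptides encoded by those exons disappear in
that genotype's channels while the remaining isoform's peptides
persist.

Everything downstream (quantification, differential testing, classifier
training, proteoform fingerprinting) can be exercised against the
recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .proteoform import (
    Exon,
    GeneModel,
    Isoform,
    TrypticPeptide,
    digest_isoform,
)

META_COLUMNS = ["peptide", "protein", "is_phospho", "spec_count"]

# Residues drawn for generated sequences; K/R placed separately so the
# tryptic-fragment length distribution lands mostly in the 8-35 window.
_NON_KR = "ACDEFGHILMNPQSTVWY"
_KR_RATE = 1.0 / 15.0

CLASS_LABELS = (
    "postsynaptic", "presynaptic", "cytosolic_er", "nonsynaptic_membrane",
)

FEATURE_COLUMNS = [
    "spec_count", "sequence_coverage", "molecular_weight",
    "isoelectric_point", "log_density", "fold_pre_over_cyto",
    "fold_post_over_cyto", "norm_pre", "norm_cyto", "norm_post",
]

SILENCE_FLOOR = 1e-3  # silenced peptides keep a small positive floor


@dataclass(frozen=True)
class IsoformEffect:
    """A per-group fold applied to a subset of a protein's peptides
    (indices into the protein's peptide list)."""

    peptide_indices: tuple[int, ...]
    fold_by_group: Mapping[str, float]


@dataclass
class SimulationDesign:
    """Design of one simulated multiplexed experiment.

    ``group_labels`` assigns each channel to a group (cell type x
    genotype); ``effect_table`` injects protein-level fold changes per
    group; ``isoform_effect_table`` injects peptide-subset folds that
    model isoform divergence; ``exon_deletions`` silences, per group,
    the peptides of gene-model proteins that require deleted exons.
    """

    group_labels: Sequence[str]
    n_proteins: int = 20
    n_peptides_per_protein: tuple[int, int] = (4, 10)
    noise_cv: float = 0.2
    effect_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    isoform_effect_table: Mapping[str, Sequence[IsoformEffect]] = field(
        default_factory=dict)
    exon_deletions: Mapping[str, Mapping[str, Sequence[str]]] = field(
        default_factory=dict)
    phospho_fraction: float = 0.2
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.group_labels)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def channel_names(self) -> list[str]:
        counts: dict[str, int] = {}
        names = []
        for g in self.group_labels:
            counts[g] = counts.get(g, 0) + 1
            names.append(f"{g}_{counts[g]}")
        return names

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("at least one channel required")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        for prot, folds in self.effect_table.items():
            for g, f in folds.items():
                if f <= 0:
                    raise ValueError(
                        f"fold for {prot}/{g} must be strictly positive")
        lo, hi = self.n_peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_peptides_per_protein range")
        for prot, effects in self.isoform_effect_table.items():
            for eff in effects:
                for g, f in eff.fold_by_group.items():
                    if f <= 0:
                        raise ValueError(
                            f"isoform fold for {prot}/{g} must be positive")
                if any(i < 0 or i >= hi for i in eff.peptide_indices):
                    raise ValueError(
                        f"peptide indices for {prot} outside peptide range")


@dataclass
class GroundTruth:
    """Every injected effect, recoverable without generator internals."""

    true_fold: pd.DataFrame  # protein x group
    true_isoform_divergent: dict[str, bool]
    silenced_peptides: dict[tuple[str, str], frozenset[str]]
    true_class: pd.Series | None = None
    true_isoform_present: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=dict)


def _random_segment(rng: np.random.Generator, length: int) -> str:
    kr = rng.random(length) < _KR_RATE
    body = rng.choice(list(_NON_KR), size=length)
    which = rng.choice(["K", "R"], size=length)
    return "".join(
        which[i] if kr[i] else body[i] for i in range(length)
    )


def make_gene_model(n_exons: int, exon_len_range: tuple[int, int] = (20, 60),
                    n_isoforms: int = 2, seed: int = 0,
                    gene_id: str = "GENE",
                    start_exons: Sequence[str] | None = None) -> GeneModel:
    """A gene model with ordered exons and truncation isoforms.

    The first isoform spans the full exon chain; subsequent isoforms
    start at internal exons, modeling alternative transcription starts.
    Start exons default to positions spaced evenly through the gene and
    can be given explicitly via ``start_exons`` (overrides
    ``n_isoforms``).  Fixed seed gives a byte-identical model on repeat
    calls.
    """
    if n_exons < 2:
        raise ValueError("n_exons must be >= 2")
    if n_isoforms < 1:
        raise ValueError("n_isoforms must be >= 1")
    lo, hi = exon_len_range
    if lo <= 0 or hi < lo:
        raise ValueError("exon lengths must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    exons = tuple(
        Exon(str(i + 1), _random_segment(rng, int(rng.integers(lo, hi + 1))))
        for i in range(n_exons)
    )
    exon_ids = tuple(e.id for e in exons)
    isoforms = [Isoform(f"{gene_id}_full", exon_ids)]
    if start_exons is not None:
        unknown = [s for s in start_exons if s not in exon_ids]
        if unknown:
            raise ValueError(f"unknown start exons: {unknown}")
        starts = [exon_ids.index(s) for s in start_exons]
    elif n_isoforms > 1:
        starts = np.linspace(1, n_exons - 1, n_isoforms - 1, dtype=int)
        starts = sorted(set(int(s) for s in starts))[: n_isoforms - 1]
    else:
        starts = []
    for s in starts:
        if s == 0:
            raise ValueError("truncation isoforms must start at an "
                             "internal exon")
        isoforms.append(
            Isoform(f"{gene_id}_from_{exon_ids[s]}", exon_ids[s:])
        )
    return GeneModel(gene_id=gene_id, exons=exons, isoforms=tuple(isoforms))


def delete_exons(model: GeneModel, exon_ids: Sequence[str]) -> GeneModel:
    """Genotype variant with the listed exons removed.

    Isoforms requiring any deleted exon are marked untranslatable;
    isoforms not overlapping the deletion are unchanged.
    """
    known = set(model.exon_ids)
    unknown = [e for e in exon_ids if e not in known]
    if unknown:
        raise ValueError(f"unknown exon ids: {unknown}")
    dropped = set(exon_ids)
    if not dropped:
        return model
    new_exons = tuple(e for e in model.exons if e.id not in dropped)
    new_isoforms = tuple(
        replace(iso, untranslatable=True)
        if (set(iso.exon_ids) & dropped) and not iso.untranslatable
        else iso
        for iso in model.isoforms
    )
    return GeneModel(model.gene_id, new_exons, new_isoforms)


def _gene_peptides(model: GeneModel) -> dict[str, set[str]]:
    """Peptide sequences per translatable isoform of a model."""
    out: dict[str, set[str]] = {}
    for iso in model.isoforms:
        if iso.untranslatable:
            continue
        out[iso.name] = {p.sequence for p in digest_isoform(model, iso.name)}
    return out


def simulate_experiment(design: SimulationDesign,
                        models: Sequence[GeneModel] = (),
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Peptide-level reporter-ion table plus ground truth.

    Per peptide and channel, intensity = baseline x protein group fold x
    isoform-subset fold x log-normal noise.  Peptides that belong only
    to isoforms silenced by an exon deletion in a group's genotype drop
    to a small positive floor in that group's channels.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    channels = design.channel_names
    groups = list(design.group_labels)
    sigma = float(np.sqrt(np.log1p(design.noise_cv ** 2)))

    rows: list[dict] = []
    lo, hi = design.n_peptides_per_protein
    silenced: dict[tuple[str, str], frozenset[str]] = {}
    iso_divergent: dict[str, bool] = {}
    iso_present: dict[tuple[str, str], tuple[str, ...]] = {}
    protein_names: list[str] = []

    def emit(protein: str, pep_seq: str, factors: dict[str, float]) -> None:
        base = 10.0 ** rng.uniform(4.0, 6.0)
        noise = (
            np.exp(rng.normal(-0.5 * sigma ** 2, sigma, design.n_channels))
            if sigma > 0 else np.ones(design.n_channels)
        )
        row = {
            "peptide": pep_seq,
            "protein": protein,
            "is_phospho": bool(rng.random() < design.phospho_fraction),
            "spec_count": int(rng.poisson(5) + 1),
        }
        for j, ch in enumerate(channels):
            row[ch] = base * factors[groups[j]] * noise[j]
        rows.append(row)

    # generic proteins with optional protein-level and subset-level folds
    for i in range(design.n_proteins):
        prot = f"P{i:04d}"
        protein_names.append(prot)
        n_pep = int(rng.integers(lo, hi + 1))
        pep_seqs = [
            _random_segment(rng, int(rng.integers(7, 20))) + "K"
            for _ in range(n_pep)
        ]
        prot_folds = design.effect_table.get(prot, {})
        effects = design.isoform_effect_table.get(prot, ())
        divergent = False
        for k, pep in enumerate(pep_seqs):
            factors = {g: prot_folds.get(g, 1.0) for g in design.groups}
            for eff in effects:
                if k in eff.peptide_indices:
                    for g, f in eff.fold_by_group.items():
                        factors[g] *= f
            emit(prot, pep, factors)
        for eff in effects:
            vals = set(eff.fold_by_group.values())
            if len(vals | {1.0}) > 1 and eff.peptide_indices:
                divergent = True
        iso_divergent[prot] = divergent

    # gene-model proteins: genotype-specific exon deletions silence the
    # peptides that no surviving isoform of that genotype encodes
    for model in models:
        prot = model.gene_id
        protein_names.append(prot)
        ref_iso = _gene_peptides(model)
        all_peps = sorted(set().union(*ref_iso.values())) if ref_iso else []
        group_variants: dict[str, dict[str, set[str]]] = {}
        for g in design.groups:
            deleted = design.exon_deletions.get(g, {}).get(prot, ())
            variant = delete_exons(model, list(deleted)) if deleted else model
            group_variants[g] = _gene_peptides(variant)
            iso_present[(g, prot)] = tuple(sorted(group_variants[g]))
        divergent = False
        for g in design.groups:
            alive = set().union(*group_variants[g].values()) \
                if group_variants[g] else set()
            lost = frozenset(p for p in all_peps if p not in alive)
            silenced[(prot, g)] = lost
            if lost:
                divergent = True
        iso_divergent[prot] = divergent
        for pep in all_peps:
            factors = {
                g: SILENCE_FLOOR if pep in silenced[(prot, g)] else 1.0
                for g in design.groups
            }
            emit(prot, pep, factors)

    table = pd.DataFrame(rows, columns=META_COLUMNS + channels)

    fold = pd.DataFrame(1.0, index=protein_names, columns=design.groups)
    for prot, folds in design.effect_table.items():
        for g, f in folds.items():
            if prot in fold.index:
                fold.loc[prot, g] = f
    truth = GroundTruth(
        true_fold=fold,
        true_isoform_divergent=iso_divergent,
        silenced_peptides=silenced,
        true_isoform_present=iso_present,
    )
    return table, truth


def simulate_classifier_proteome(n_per_class: int, separation: float,
                                 seed: int = 0
                                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """Ten-feature table for synaptic-class classification.

    Postsynaptic proteins are enriched in the postsynaptic-probe channel
    (high post/cyto fold) and presynaptic proteins in the presynaptic-
    probe channel; ``separation`` scales the log-fold offset between the
    enriched class and the rest, so separation 0 makes the classes
    indistinguishable.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    rng = np.random.default_rng(seed)
    frames = []
    labels = []
    genes = []
    for cls in CLASS_LABELS:
        n = n_per_class
        post_shift = separation if cls == "postsynaptic" else 0.0
        pre_shift = separation if cls == "presynaptic" else 0.0
        log2_fold_post = rng.normal(post_shift, 1.0, n)
        log2_fold_pre = rng.normal(pre_shift, 1.0, n)
        norm_cyto = 10.0 ** rng.uniform(4.0, 6.0, n)
        jitter = np.exp(rng.normal(0.0, 0.1, (2, n)))
        norm_post = norm_cyto * 2.0 ** log2_fold_post * jitter[0]
        norm_pre = norm_cyto * 2.0 ** log2_fold_pre * jitter[1]
        length = rng.integers(200, 2000, n)
        frames.append(pd.DataFrame({
            "spec_count": rng.poisson(20, n) + 2,
            "sequence_coverage": rng.beta(2.0, 2.0, n),
            "molecular_weight": length * 0.110,
            "isoelectric_point": np.clip(rng.normal(7.0, 1.5, n), 4.0, 12.0),
            "log_density": np.log10(
                (norm_pre + norm_cyto + norm_post) / length),
            "fold_pre_over_cyto": norm_pre / norm_cyto,
            "fold_post_over_cyto": norm_post / norm_cyto,
            "norm_pre": norm_pre,
            "norm_cyto": norm_cyto,
            "norm_post": norm_post,
        }))
        labels.extend([cls] * n)
        genes.extend(f"{cls[:4].upper()}{i:04d}" for i in range(n))
    features = pd.concat(frames, ignore_index=True)[FEATURE_COLUMNS]
    features.index = pd.Index(genes, name="gene")
    true_class = pd.Series(labels, index=features.index, name="true_class")
    truth = GroundTruth(
        true_fold=pd.DataFrame(index=features.index),
        true_isoform_divergent={},
        silenced_peptides={},
        true_class=true_class,
    )
    return features, truth


def simulate_isoform_detections(model: GeneModel, isoform_name: str,
                                dropout: float = 0.0, seed: int = 0
                                ) -> list[TrypticPeptide]:
    """Detected (labeled) peptides of one expressed isoform with random
    detection dropout, emulating incomplete MS sampling."""
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    peptides = digest_isoform(model, isoform_name)
    kept = [p for p in peptides if rng.random() >= dropout]
    if not kept and peptides:
        kept = [peptides[int(rng.integers(len(peptides)))]]
    return kept
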