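"""Supervised construction of a postsynaptic proteome library.

Training labels are assembled from two annotation sources: a broad
postsynaptic database (deep but containing misclassified presynaptic
entries) and a curated database split into pre- and postsynaptic sets.
Genes curated as both pre- and postsynaptic count as postsynaptic; the
exclusively-presynaptic set is subtracted from the broad database, and
the cleaned broad set is merged with the curated postsynaptic set to
form the positive class.  A random forest over ten quantitative and
physicochemical features scores every quantified protein, and the final
library keeps proteins classified postsynaptic in at least two
independent experiments.  Library purity is summarized as the fraction
of included genes annotated non-synaptic membrane or exclusively
presynaptic (class-specific false discovery rates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .quantify import channel_columns, sum_protein_intensities
from .synthetic_data import FEATURE_COLUMNS
from .proteoform import theoretical_mw

POSITIVE_LABEL = "postsynaptic"
NEGATIVE_LABEL = "non_postsynaptic"


@dataclass(frozen=True)
class AnnotationSets:
    """Gene sets over one identifier namespace: a broad postsynaptic
    database, curated pre/postsynaptic sets, and the contaminant sets
    used for normalization and FDR estimation."""

    broad_postsynaptic: frozenset[str]
    curated_presynaptic: frozenset[str]
    curated_postsynaptic: frozenset[str]
    nonsynaptic_membrane: frozenset[str] = frozenset()
    cytosolic_er: frozenset[str] = frozenset()

    @property
    def exclusive_presynaptic(self) -> frozenset[str]:
        """Curated presynaptic genes not also curated postsynaptic
        (dual-annotated genes count as postsynaptic)."""
        return self.curated_presynaptic - self.curated_postsynaptic


def build_training_set(ann: AnnotationSets,
                       universe: Iterable[str] | None = None
                       ) -> pd.DataFrame:
    """Labeled training genes.

    Positives = (broad postsynaptic minus exclusively-presynaptic)
    union curated postsynaptic.  Negatives = exclusively-presynaptic
    union non-synaptic membrane union cytosolic/ER, minus positives.
    With a ``universe`` of quantified genes supplied, training genes are
    restricted to it and zero overlap raises (identifier namespace
    mismatch).
    """
    if not ann.broad_postsynaptic and not ann.curated_postsynaptic:
        raise ValueError("no postsynaptic annotation supplied")
    cleaned_broad = ann.broad_postsynaptic - ann.exclusive_presynaptic
    positives = cleaned_broad | ann.curated_postsynaptic
    negatives = (
        ann.exclusive_presynaptic
        | ann.nonsynaptic_membrane
        | ann.cytosolic_er
    ) - positives
    if universe is not None:
        universe = set(universe)
        if not (positives | negatives) & universe:
            raise ValueError(
                "annotation gene identifiers do not overlap the quantified "
                "table: identifier namespace mismatch")
        positives &= universe
        negatives &= universe
    rows = [{"gene": g, "label": POSITIVE_LABEL} for g in sorted(positives)]
    rows += [{"gene": g, "label": NEGATIVE_LABEL} for g in sorted(negatives)]
    return pd.DataFrame(rows, columns=["gene", "label"])


def _coverage(sequence: str, peptide_seqs: Iterable[str]) -> float:
    """Fraction of residues covered by the union of peptide matches."""
    covered = np.zeros(len(sequence), dtype=bool)
    for pep in peptide_seqs:
        start = 0
        while True:
            i = sequence.find(pep, start)
            if i < 0:
                break
            covered[i:i + len(pep)] = True
            start = i + 1
    return float(covered.mean()) if len(sequence) else 0.0


def isoelectric_point(sequence: str) -> float:
    """pI by bisection on the Henderson-Hasselbalch charge sum."""
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    return float(IsoelectricPoint(sequence).pi())


def extract_features(peptides: pd.DataFrame,
                     channel_roles: Mapping[str, str],
                     sequences: Mapping[str, str],
                     proteins: pd.DataFrame | None = None,
                     min_peptides: int = 2) -> pd.DataFrame:
    """Ten-feature table per gene for classification.

    ``channel_roles`` maps the probe roles ``pre``, ``cyto`` and
    ``post`` to channel column names of ``proteins`` (a normalized
    protein table; recomputed from ``peptides`` when omitted).
    Proteins with fewer than ``min_peptides`` quantified peptides are
    dropped; for genes with several isoform accessions only the
    accession with the highest total intensity is kept.  Molecular
    weight (average masses) and isoelectric point are computed from the
    protein sequence.
    """
    for role in ("pre", "cyto", "post"):
        if role not in channel_roles:
            raise ValueError(f"channel_roles must define {role!r}")
    if proteins is None:
        proteins = sum_protein_intensities(peptides)
    channels = channel_columns(proteins)
    proteins = proteins[proteins["n_peptides"] >= min_peptides]
    from .differential import select_primary_accession

    proteins = select_primary_accession(proteins)
    missing = [a for a in proteins["protein"] if a not in sequences]
    if missing:
        raise ValueError(f"no sequence for accessions: {missing}")

    pep_by_acc: dict[str, list[pd.Series]] = {}
    for _, row in peptides.iterrows():
        for acc in str(row["protein"]).split(";"):
            pep_by_acc.setdefault(acc.strip(), []).append(row)

    pre_c, cyto_c, post_c = (channel_roles[r] for r in
                             ("pre", "cyto", "post"))
    rows = []
    for _, prow in proteins.iterrows():
        acc = prow["protein"]
        seq = sequences[acc]
        members = pep_by_acc.get(acc, [])
        spec_count = int(sum(r["spec_count"] for r in members))
        coverage = _coverage(seq, (r["peptide"] for r in members))
        total = float(prow[channels].sum())
        rows.append({
            "gene": prow["gene"],
            "protein": acc,
            "spec_count": spec_count,
            "sequence_coverage": coverage,
            "molecular_weight": theoretical_mw(seq),
            "isoelectric_point": isoelectric_point(seq),
            "log_density": np.log10(total / len(seq)),
            "fold_pre_over_cyto": prow[pre_c] / prow[cyto_c],
            "fold_post_over_cyto": prow[post_c] / prow[cyto_c],
            "norm_pre": prow[pre_c],
            "norm_cyto": prow[cyto_c],
            "norm_post": prow[post_c],
        })
    out = pd.DataFrame(rows).set_index("gene")
    return out[["protein"] + FEATURE_COLUMNS]


def train_and_classify(features: pd.DataFrame, labels: pd.Series,
                       n_estimators: int = 500, seed: int = 0,
                       n_folds: int = 5) -> pd.Series:
    """Random-forest postsynaptic score for every row of ``features``.

    Labeled rows receive out-of-fold scores (stratified K-fold) so
    downstream ROC evaluation is free of training-set leakage;
    unlabeled rows are scored by a forest fit on all labeled rows.
    Deterministic under a fixed seed.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    if len(cols) != len(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(cols)
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    labels = labels.dropna()
    classes = set(labels.unique())
    if len(classes) < 2:
        raise ValueError("training labels must contain both classes")
    X = features[cols]
    labeled = features.index.intersection(labels.index)
    Xl = X.loc[labeled].to_numpy(dtype=float)
    yl = (labels.loc[labeled] == POSITIVE_LABEL).to_numpy()

    scores = pd.Series(np.nan, index=features.index, name="score")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(len(labeled))
    for train_idx, test_idx in skf.split(Xl, yl):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=seed,
        ).fit(Xl[train_idx], yl[train_idx])
        oof[test_idx] = rf.predict_proba(Xl[test_idx])[:, 1]
    scores.loc[labeled] = oof

    unlabeled = features.index.difference(labels.index)
    if len(unlabeled):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=seed,
        ).fit(Xl, yl)
        scores.loc[unlabeled] = rf.predict_proba(
            X.loc[unlabeled].to_numpy(dtype=float))[:, 1]
    return scores


def roc_curve_auc(scores, labels
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoid AUROC."""
    from sklearn.metrics import auc, roc_curve

    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, thresholds = roc_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr, thresholds, float(auc(fpr, tpr))


def assemble_library(per_experiment_scores: pd.DataFrame,
                     threshold: float = 0.5) -> pd.DataFrame:
    """Library entries from per-experiment classifier scores
    (genes x experiments); inclusion requires a postsynaptic call
    (score >= threshold) in at least two experiments."""
    if per_experiment_scores.shape[1] < 2:
        raise ValueError("at least two experiments required")
    positive = per_experiment_scores >= threshold
    n_pos = positive.sum(axis=1)
    out = per_experiment_scores.copy()
    out["n_experiments_positive"] = n_pos
    out["included"] = n_pos >= 2
    out.index.name = "gene"
    return out


def estimate_library_fdr(library: pd.DataFrame, ann: AnnotationSets
                         ) -> dict[str, float]:
    """Class-specific contamination of the included library: fraction
    annotated non-synaptic membrane and fraction annotated exclusively
    presynaptic."""
    if library.empty:
        raise ValueError("library is empty")
    included = library[library["included"]] if "included" in library \
        else library
    genes = set(included.index)
    n = len(genes)
    if n == 0:
        return {"fdr_nonsynaptic_membrane": 0.0, "fdr_presynaptic": 0.0}
    return {
        "fdr_nonsynaptic_membrane":
            len(genes & ann.nonsynaptic_membrane) / n,
        "fdr_presynaptic":
            len(genes & ann.exclusive_presynaptic) / n,
    }
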