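"""Reporter-ion quantification: peptide -> protein roll-up, reference
normalization, and compositional phosphopeptide renormalization.

Protein abundance per channel is the sum of its peptides' reporter-ion
intensities.  Channels are made comparable by dividing each channel by
the median intensity of a reference set of cytosolic / endoplasmic-
reticulum proteins (whose true abundance should not differ between
probes), then rescaling by the grand mean of the factors so magnitudes
stay on the original scale.  Phosphopeptide analysis renormalizes all
peptides of a protein within each channel to a fixed total of 2,000,000
so phosphosite changes are read relative to the protein's own signal.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic_data import META_COLUMNS

PHOSPHO_TOTAL = 2_000_000.0
ACCESSION_DELIMITER = ";"

PROTEIN_META = ["protein", "gene", "n_peptides"]


def channel_columns(table: pd.DataFrame) -> list[str]:
    """Channel (intensity) columns of a peptide or protein table."""
    meta = set(META_COLUMNS) | set(PROTEIN_META)
    return [c for c in table.columns if c not in meta]


def _default_gene(accession: str) -> str:
    return accession.split("-")[0]


def sum_protein_intensities(peptides: pd.DataFrame,
                            gene_map: Mapping[str, str] | None = None
                            ) -> pd.DataFrame:
    """Per-protein, per-channel summed reporter-ion intensities.

    Peptides assigned to multiple accessions (delimiter ``;``)
    contribute to every listed accession — no razor-peptide logic.
    ``gene_map`` maps accession to gene symbol; by default the accession
    up to the first ``-`` is used (isoform-accession convention).
    Returns a table with columns protein, gene, n_peptides and one
    summed-intensity column per channel.  An empty input yields an
    empty result with the channel schema preserved.
    """
    channels = channel_columns(peptides)
    if peptides.empty:
        return pd.DataFrame(columns=PROTEIN_META + channels)
    if (peptides[channels].to_numpy() < 0).any():
        raise ValueError("negative intensities in peptide table")
    expanded = peptides.assign(
        protein=peptides["protein"].str.split(ACCESSION_DELIMITER)
    ).explode("protein")
    expanded["protein"] = expanded["protein"].str.strip()
    if expanded.empty:
        return pd.DataFrame(columns=PROTEIN_META + channels)
    grouped = expanded.groupby("protein", sort=True)
    out = grouped[channels].sum()
    out.insert(0, "n_peptides", grouped["peptide"].nunique())
    out = out.reset_index()
    if gene_map is None:
        out.insert(1, "gene", out["protein"].map(_default_gene))
    else:
        out.insert(1, "gene", out["protein"].map(
            lambda a: gene_map.get(a, _default_gene(a))))
    return out[["protein", "gene", "n_peptides"] + channels]


def normalize_channels(proteins: pd.DataFrame,
                       reference: Iterable[str]) -> pd.DataFrame:
    """Divide each channel by the median intensity of the reference
    (cytosolic/ER) proteins, then rescale by the grand mean of the
    per-channel factors so absolute magnitudes remain comparable.

    After normalization the median intensity of reference proteins is
    equal across channels.  The operation is idempotent to floating
    tolerance.
    """
    reference = set(reference)
    channels = channel_columns(proteins)
    mask = proteins["protein"].isin(reference)
    if "gene" in proteins.columns:
        mask = mask | proteins["gene"].isin(reference)
    if not mask.any():
        raise ValueError(
            "no reference protein quantified; missing reference set: "
            f"{sorted(reference)[:10]}{' ...' if len(reference) > 10 else ''}")
    factors = proteins.loc[mask, channels].median(axis=0)
    if (factors <= 0).any():
        bad = list(factors.index[factors <= 0])
        raise ValueError(f"non-positive reference median in channels {bad}")
    out = proteins.copy()
    out[channels] = proteins[channels] / factors * factors.mean()
    return out


def renormalize_phospho(peptides_of_protein: pd.DataFrame,
                        total: float = PHOSPHO_TOTAL) -> pd.DataFrame:
    """Compositional renormalization of one protein's peptides.

    Per channel, each peptide's value becomes
    ``intensity / sum(all peptides of the protein) * total`` with
    missing values treated as 0, so every channel with signal sums to
    exactly ``total`` (2,000,000 by default).  A channel with no signal
    at all stays all-zero rather than raising.
    """
    accs = peptides_of_protein["protein"].unique()
    if len(accs) != 1:
        raise ValueError(
            f"renormalize_phospho expects a single accession, got {accs}")
    channels = channel_columns(peptides_of_protein)
    out = peptides_of_protein.copy()
    vals = out[channels].fillna(0.0).to_numpy(dtype=float)
    sums = vals.sum(axis=0)
    scale = np.divide(total, sums, out=np.zeros_like(sums), where=sums > 0)
    out[channels] = vals * scale
    return out
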