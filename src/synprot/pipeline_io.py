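"""File formats, run configuration, and the end-to-end pipeline.

Formats are deliberately plain: peptide tables as TSV, protein
sequences as FASTA, gene models as JSON, annotation gene lists as one
symbol per line, configuration as YAML.  Every output TSV is
accompanied by a sidecar ``<name>.schema.json`` describing its columns.

``run_pipeline`` chains the stages — quantification and normalization,
optional restriction to a postsynaptic library, protein- and
isoform-level differential testing, and proteoform fingerprinting for
configured multi-isoform genes — and writes a machine-readable run log.
All randomness flows from the single config seed, so identical config
and inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .quantify import (
    channel_columns,
    normalize_channels,
    sum_protein_intensities,
)
from .differential import differential_table, peptide_fold_profile
from .proteoform import (
    GeneModel,
    TrypticPeptide,
    assign_isoform,
    exon_frequency_table,
    map_peptide_to_exons,
    standard_tables,
    translate_isoform,
)

REQUIRED_PEPTIDE_COLUMNS = ["peptide", "protein", "is_phospho", "spec_count"]


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Parse and validate a TSV peptide quantification table.

    The header must contain peptide, protein, is_phospho, spec_count
    followed by one intensity column per channel; malformed rows are
    reported with their line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in REQUIRED_PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}")
    channels = [c for c in table.columns
                if c not in REQUIRED_PEPTIDE_COLUMNS]
    if not channels:
        raise ValueError(f"{path}: no intensity channel columns found")
    bad_lines = []
    for col in channels + ["spec_count"]:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() | (vals < 0)]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header, 1-based
        table[col] = vals
    if bad_lines:
        raise ValueError(
            f"{path}: negative or non-numeric intensities at lines "
            f"{sorted(set(bad_lines))}")
    table["is_phospho"] = table["is_phospho"].astype(bool)
    table["spec_count"] = table["spec_count"].astype(int)
    return table


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession (first header token) -> upper-case sequence."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out[rec.id.split()[0]] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for acc in sequences:
            fh.write(f">{acc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gene_model(path: str | Path) -> GeneModel:
    return GeneModel.from_json(Path(path).read_text())


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(model.to_json() + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def write_gene_list(genes, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(sorted(genes)) + "\n")


_SCHEMAS = {
    "proteins": {
        "protein": "accession", "gene": "gene symbol",
        "n_peptides": "number of distinct quantified peptides",
        "*": "summed reporter-ion intensity per channel",
    },
    "normalized": {
        "protein": "accession", "gene": "gene symbol",
        "n_peptides": "number of distinct quantified peptides",
        "*": "reference-normalized intensity per channel",
    },
    "differential": {
        "protein": "accession", "gene": "gene symbol",
        "mean_fold": "group1/group2 ratio of group means",
        "p_protein": "one-tailed Welch t-test p-value",
        "p_genotype": "two-way ANOVA genotype main-effect p-value",
        "p_peptide": "two-way ANOVA peptide main-effect p-value",
        "p_interaction": "two-way ANOVA genotype x peptide p-value",
        "isoform_assessable": ">=2 peptides available",
        "is_protein_divergent": "p_protein < alpha",
        "is_isoform_divergent": "p_interaction < alpha",
        "q_protein": "Benjamini-Hochberg adjusted p_protein",
        "q_interaction": "Benjamini-Hochberg adjusted p_interaction",
    },
    "proteoform": {
        "group": "sample group", "rank": "candidate rank (1 = nearest)",
        "isoform": "candidate isoform", "distance":
        "Euclidean distance between union-aligned frequency vectors",
    },
}


def _write_tsv(df: pd.DataFrame, path: Path, schema_key: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    schema = _SCHEMAS.get(schema_key, {})
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps({"columns": schema}, indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: Path
    peptide_table: Path | None = None
    channel_groups: dict[str, list[str]] = field(default_factory=dict)
    reference_proteins: Path | None = None
    library_genes: Path | None = None
    gene_models: list[Path] = field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0
    plots: bool = False
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent

        def p(key):
            return (base / raw[key]) if key in raw and raw[key] else None

        cfg = cls(
            output_dir=base / raw.get("output_dir", "results"),
            peptide_table=p("peptide_table"),
            channel_groups={
                str(g): list(chs)
                for g, chs in (raw.get("channel_groups") or {}).items()
            },
            reference_proteins=p("reference_proteins"),
            library_genes=p("library_genes"),
            gene_models=[base / m for m in raw.get("gene_models", [])],
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
            plots=bool(raw.get("plots", False)),
            simulate=raw.get("simulate"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if self.peptide_table is None:
                raise ValueError(
                    "config must provide peptide_table or a simulate block")
            if not self.channel_groups:
                raise ValueError("config must provide channel_groups")
            for path in filter(None, [self.peptide_table,
                                      self.reference_proteins,
                                      self.library_genes, *self.gene_models]):
                if not Path(path).exists():
                    raise FileNotFoundError(f"configured path {path} missing")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


def _simulate_inputs(config: RunConfig) -> None:
    """Generate pipeline inputs from the config's simulate block and
    rewrite the config fields to point at them."""
    from . import synthetic_data as sd

    block = dict(config.simulate or {})
    groups: dict[str, int] = block.get("groups", {"g1": 5, "g2": 5})
    labels = [g for g, n in groups.items() for _ in range(int(n))]
    gene_block = block.get("gene")
    models = []
    exon_deletions: dict[str, dict[str, list[str]]] = {}
    if gene_block:
        model = sd.make_gene_model(
            n_exons=int(gene_block.get("n_exons", 22)),
            n_isoforms=int(gene_block.get("n_isoforms", 2)),
            seed=config.seed,
            gene_id=str(gene_block.get("gene_id", "GENE")),
            start_exons=gene_block.get("start_exons"),
        )
        models.append(model)
        deleted = gene_block.get("deleted_exons") or []
        for g in gene_block.get("deleted_in_groups", []):
            exon_deletions.setdefault(str(g), {})[model.gene_id] = [
                str(e) for e in deleted]
    effect_table = {
        str(prot): {str(g): float(f) for g, f in folds.items()}
        for prot, folds in (block.get("effects") or {}).items()
    }
    design = sd.SimulationDesign(
        group_labels=labels,
        n_proteins=int(block.get("n_proteins", 20)),
        noise_cv=float(block.get("noise_cv", 0.2)),
        effect_table=effect_table,
        exon_deletions=exon_deletions,
        seed=config.seed,
    )
    table, _ = sd.simulate_experiment(design, models)
    inputs = config.output_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_peptide_table(table, inputs / "peptides.tsv")
    config.peptide_table = inputs / "peptides.tsv"
    config.channel_groups = {}
    for g, ch in zip(design.group_labels, design.channel_names):
        config.channel_groups.setdefault(g, []).append(ch)
    ref = block.get("reference_proteins")
    if ref is None:
        # default reference: generic proteins without injected effects
        ref = sorted(
            f"P{i:04d}" for i in range(design.n_proteins)
            if f"P{i:04d}" not in effect_table
        )[: max(5, design.n_proteins // 2)]
    write_gene_list(ref, inputs / "reference.txt")
    config.reference_proteins = inputs / "reference.txt"
    for model in models:
        path = inputs / f"{model.gene_id}.json"
        write_gene_model(model, path)
        config.gene_models.append(path)


def _profile_gene(model: GeneModel, peptides: pd.DataFrame,
                  channel_groups: Mapping[str, Sequence[str]],
                  seed: int) -> pd.DataFrame:
    """Per-group proteoform assignment for one gene model.

    A peptide counts as detected in a group when its mean intensity
    there is at least 5% of its best group mean — silenced peptides
    (orders of magnitude down) drop out, retained ones stay.
    """
    full_name = model.isoforms[0].name
    seq, residue_map = translate_isoform(model, full_name)
    sub = peptides[peptides["protein"] == model.gene_id]
    standards = standard_tables(model)
    rows = []
    group_means = {
        g: sub[list(chs)].mean(axis=1) for g, chs in channel_groups.items()
    }
    best = pd.concat(group_means, axis=1).max(axis=1)
    for g in channel_groups:
        detected: list[TrypticPeptide] = []
        for idx, row in sub.iterrows():
            if group_means[g].loc[idx] < 0.05 * best.loc[idx]:
                continue
            i = seq.find(row["peptide"])
            if i < 0:
                continue
            pep = TrypticPeptide(row["peptide"], i + 1, i + len(row["peptide"]))
            label = map_peptide_to_exons(pep, residue_map)
            detected.append(TrypticPeptide(
                pep.sequence, pep.start, pep.end, label))
        if not detected:
            continue
        observed = exon_frequency_table(detected)
        assignment = assign_isoform(observed, standards, seed=seed)
        for rank, (iso, dist) in enumerate(assignment.ranking, start=1):
            rows.append({"group": g, "rank": rank, "isoform": iso,
                         "distance": dist})
    return pd.DataFrame(rows, columns=["group", "rank", "isoform",
                                       "distance"])


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute quantify -> library filter -> differential -> proteoform
    profiling and write results under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None and config.peptide_table is None:
        _simulate_inputs(config)

    peptides = read_peptide_table(config.peptide_table)
    groups = list(config.channel_groups)
    channel_order = [c for g in groups for c in config.channel_groups[g]]
    known = set(channel_columns(peptides))
    missing = [c for c in channel_order if c not in known]
    if missing:
        raise ValueError(f"channel map names unknown channels {missing}")
    labels = [g for g in groups for _ in config.channel_groups[g]]

    outputs: dict[str, Path] = {}
    proteins = sum_protein_intensities(peptides)
    _write_tsv(proteins, out / "proteins.tsv", "proteins")
    outputs["proteins"] = out / "proteins.tsv"

    if config.reference_proteins:
        reference = read_gene_list(config.reference_proteins)
        normalized = normalize_channels(proteins, reference)
    else:
        normalized = proteins
    _write_tsv(normalized, out / "normalized.tsv", "normalized")
    outputs["normalized"] = out / "normalized.tsv"

    if config.library_genes:
        library = read_gene_list(config.library_genes)
        normalized = normalized[normalized["gene"].isin(library)]

    meta = ["protein", "gene", "n_peptides"]
    ordered = normalized[meta + channel_order]
    pep_ordered = peptides[REQUIRED_PEPTIDE_COLUMNS + channel_order]
    diff = differential_table(ordered, pep_ordered, labels,
                              alpha=config.alpha)
    _write_tsv(diff, out / "differential.tsv", "differential")
    outputs["differential"] = out / "differential.tsv"

    for model_path in config.gene_models:
        model = read_gene_model(model_path)
        prof = _profile_gene(model, pep_ordered, config.channel_groups,
                             config.seed)
        name = f"proteoform_{model.gene_id}.tsv"
        _write_tsv(prof, out / name, "proteoform")
        outputs[f"proteoform_{model.gene_id}"] = out / name

    if config.plots:
        _make_plots(diff, pep_ordered, labels, out)

    log = {
        "synprot_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "alpha": config.alpha,
        "channel_groups": {g: list(c)
                           for g, c in config.channel_groups.items()},
        "inputs": {
            "peptide_table": str(config.peptide_table),
            "reference_proteins": str(config.reference_proteins),
            "library_genes": str(config.library_genes),
            "gene_models": [str(m) for m in config.gene_models],
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n")
    outputs["run_log"] = out / "run_log.json"
    return outputs


def _make_plots(diff: pd.DataFrame, peptides: pd.DataFrame,
                labels: Sequence[str], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ok = diff["p_protein"].notna() & (diff["mean_fold"] > 0)
    ax.scatter(np.log2(diff.loc[ok, "mean_fold"]),
               -np.log10(diff.loc[ok, "p_protein"]), s=8)
    ax.set_xlabel("log2 fold (group1/group2)")
    ax.set_ylabel("-log10 p (one-tailed t)")
    fig.savefig(out / "volcano.png", dpi=120)
    plt.close(fig)

    assessable = diff[diff["isoform_assessable"]]
    if len(assessable):
        top = assessable.sort_values("p_interaction").iloc[0]
        sub = peptides[peptides["protein"] == top["protein"]]
        chans = channel_columns(peptides)
        prof = peptide_fold_profile(
            sub.set_index("peptide")[chans], labels, protein=top["protein"])
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(prof.qq_theoretical, prof.qq_empirical, "o", ms=4)
        lim = [min(prof.qq_theoretical), max(prof.qq_theoretical)]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("theoretical quantile")
        ax.set_ylabel("empirical quantile")
        ax.set_title(str(top["protein"]))
        fig.savefig(out / "qq_top_interaction.png", dpi=120)
        plt.close(fig)
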