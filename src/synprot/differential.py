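"""Protein-level and isoform-level (peptide-resolved) differential
analysis of normalized reporter-ion intensities.

Two tiers of comparison:

* protein level — a one-tailed Welch t-test on per-channel protein
  intensities, with the group-mean ratio as the fold change;
* isoform level — a two-way ANOVA on log peptide intensities with
  factors Genotype (group) and Peptide.  A significant
  Genotype x Peptide interaction means the protein's peptides do not
  move together between groups, the signature of differential isoform
  usage (e.g. an exon deletion silencing a peptide subset in one cell
  type only).

The ANOVA is fitted on the log scale because reporter-ion noise is
multiplicative.  For balanced complete designs the classical closed
form is used (and equals the Type-II decomposition); unbalanced designs
fall back to an OLS fit with Type-II sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import channel_columns


@dataclass
class IsoformTestResult:
    """Two-way-ANOVA outcome for one protein's peptide matrix."""

    p_genotype: float
    p_peptide: float
    p_interaction: float
    ss_genotype: float
    ss_peptide: float
    ss_interaction: float
    ss_residual: float
    assessable: bool = True

    def is_isoform_divergent(self, alpha: float = 0.05) -> bool:
        return self.assessable and self.p_interaction < alpha


@dataclass
class PeptideFoldProfile:
    """Per-peptide fold behavior of one protein between two groups."""

    protein: str
    folds: pd.Series                 # per-peptide group1/group2 mean ratio
    log_fold_variance: float
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray
    levene_p: float


def select_primary_accession(proteins: pd.DataFrame) -> pd.DataFrame:
    """One accession per gene: the one with the highest total intensity
    summed over all channels; ties break to the lexicographically
    smallest accession."""
    if "gene" not in proteins.columns:
        raise ValueError("protein table must carry a 'gene' column")
    channels = channel_columns(proteins)
    totals = proteins[channels].sum(axis=1)
    ranked = proteins.assign(_total=totals).sort_values(
        ["gene", "_total", "protein"], ascending=[True, False, True],
        kind="mergesort",
    )
    out = ranked.drop_duplicates("gene", keep="first").drop(columns="_total")
    return out.sort_index().reset_index(drop=True)


def protein_level_test(values_g1, values_g2,
                       direction: str = "auto") -> tuple[float, float]:
    """One-tailed Welch t-test p-value and group-mean ratio.

    ``direction="greater"`` tests mean(g1) > mean(g2), ``"less"`` the
    reverse, and ``"auto"`` tests in the direction of the observed mean
    difference.  The auto convention is anticonservative under the null
    (its p-values concentrate below 0.5); calibration work should fix
    the direction.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if direction not in ("greater", "less", "auto"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "auto":
        direction = "greater" if x.mean() >= y.mean() else "less"
    res = stats.ttest_ind(x, y, equal_var=False, alternative=direction)
    fold = x.mean() / y.mean() if y.mean() != 0 else np.inf
    return float(res.pvalue), float(fold)


def _anova_balanced(cells: np.ndarray) -> IsoformTestResult:
    """Closed-form two-way ANOVA with replication on a balanced
    a x b x r array (groups x peptides x replicates)."""
    a, b, r = cells.shape
    grand = cells.mean()
    m_a = cells.mean(axis=(1, 2))
    m_b = cells.mean(axis=(0, 2))
    m_ab = cells.mean(axis=2)
    ss_a = b * r * float(((m_a - grand) ** 2).sum())
    ss_b = a * r * float(((m_b - grand) ** 2).sum())
    ss_ab = r * float(
        ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_e = float(((cells - m_ab[:, :, None]) ** 2).sum())
    df_a, df_b = a - 1, b - 1
    df_ab, df_e = df_a * df_b, a * b * (r - 1)

    def pval(ss, df):
        if df_e == 0 or ss_e == 0:
            return float("nan")
        f = (ss / df) / (ss_e / df_e)
        return float(stats.f.sf(f, df, df_e))

    return IsoformTestResult(
        p_genotype=pval(ss_a, df_a),
        p_peptide=pval(ss_b, df_b),
        p_interaction=pval(ss_ab, df_ab),
        ss_genotype=ss_a, ss_peptide=ss_b,
        ss_interaction=ss_ab, ss_residual=ss_e,
    )


def _anova_statsmodels(long: pd.DataFrame) -> IsoformTestResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(genotype) * C(peptide)", data=long).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    return IsoformTestResult(
        p_genotype=float(tab.loc["C(genotype)", "PR(>F)"]),
        p_peptide=float(tab.loc["C(peptide)", "PR(>F)"]),
        p_interaction=float(tab.loc["C(genotype):C(peptide)", "PR(>F)"]),
        ss_genotype=float(tab.loc["C(genotype)", "sum_sq"]),
        ss_peptide=float(tab.loc["C(peptide)", "sum_sq"]),
        ss_interaction=float(tab.loc["C(genotype):C(peptide)", "sum_sq"]),
        ss_residual=float(tab.loc["Residual", "sum_sq"]),
    )


def isoform_level_test(peptide_matrix: pd.DataFrame, group_labels,
                       log_transform: bool = True,
                       engine: str = "auto") -> IsoformTestResult:
    """Two-way ANOVA (Genotype, Peptide, interaction) on one protein's
    peptide x channel matrix.

    ``group_labels`` assigns each column to a group; each group needs at
    least two channels.  With a single peptide the interaction is
    undefined and the result is flagged not assessable instead of
    carrying a p-value.
    """
    labels = np.asarray(group_labels)
    if peptide_matrix.shape[1] != labels.size:
        raise ValueError("one group label per channel required")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2 or counts.min() < 2:
        raise ValueError("need >=2 groups with >=2 channels each")
    vals = peptide_matrix.to_numpy(dtype=float)
    if log_transform:
        if (vals <= 0).any():
            raise ValueError("log transform requires positive intensities")
        vals = np.log(vals)
    if vals.shape[0] < 2:
        return IsoformTestResult(
            p_genotype=float("nan"), p_peptide=float("nan"),
            p_interaction=float("nan"), ss_genotype=float("nan"),
            ss_peptide=float("nan"), ss_interaction=float("nan"),
            ss_residual=float("nan"), assessable=False,
        )
    balanced = counts.min() == counts.max()
    if engine == "auto":
        engine = "closed_form" if balanced else "statsmodels"
    if engine == "closed_form":
        if not balanced:
            raise ValueError("closed-form path requires a balanced design")
        r = int(counts[0])
        cells = np.stack(
            [vals[:, labels == g].reshape(vals.shape[0], r) for g in groups]
        )  # a x b x r
        return _anova_balanced(cells)
    if engine == "statsmodels":
        long = pd.DataFrame({
            "value": vals.ravel(),
            "peptide": np.repeat(np.arange(vals.shape[0]), vals.shape[1])
            .astype(str),
            "genotype": np.tile(labels, vals.shape[0]),
        })
        return _anova_statsmodels(long)
    raise ValueError(f"unknown engine {engine!r}")


def peptide_fold_profile(peptide_matrix: pd.DataFrame, group_labels,
                         protein: str = "") -> PeptideFoldProfile:
    """Per-peptide group-mean ratios with dispersion diagnostics.

    Returns the per-peptide fold (group1/group2 mean ratio in label
    order), the variance of log folds (large when peptide subsets move
    differently — the isoform signature), normal-quantile pairs of the
    standardized log folds for Q-Q display, and a Brown-Forsythe
    p-value testing homogeneity of within-peptide residual scale
    across peptides.
    """
    labels = np.asarray(group_labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("fold profile is defined for exactly two groups")
    vals = peptide_matrix.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("fold profile requires positive intensities")
    g1, g2 = (vals[:, labels == g] for g in groups)
    folds = pd.Series(
        g1.mean(axis=1) / g2.mean(axis=1),
        index=peptide_matrix.index, name="fold",
    )
    log_folds = np.log(folds.to_numpy())
    var = float(np.var(log_folds, ddof=1)) if log_folds.size > 1 else 0.0
    centered = log_folds - log_folds.mean()
    sd = centered.std(ddof=1) if log_folds.size > 1 else 0.0
    z = centered / sd if sd > 0 else centered
    (theo, emp), _ = stats.probplot(z, dist="norm")
    # residual-scale homogeneity across peptides (cell-centered values)
    logv = np.log(vals)
    resid_groups = []
    for p in range(logv.shape[0]):
        res = np.concatenate([
            logv[p, labels == g] - logv[p, labels == g].mean()
            for g in groups
        ])
        resid_groups.append(res)
    if len(resid_groups) > 1 and min(len(r) for r in resid_groups) > 1:
        levene_p = float(stats.levene(*resid_groups, center="median").pvalue)
    else:
        levene_p = float("nan")
    return PeptideFoldProfile(
        protein=protein, folds=folds, log_fold_variance=var,
        qq_theoretical=np.asarray(theo), qq_empirical=np.asarray(emp),
        levene_p=levene_p,
    )


def fisher_compare(counts_2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table; the
    all-zero table returns 1.0 by convention."""
    table = np.asarray(counts_2x2)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def differential_table(proteins: pd.DataFrame, peptides: pd.DataFrame,
                       group_labels, alpha: float = 0.05,
                       direction: str = "auto",
                       with_bh: bool = True) -> pd.DataFrame:
    """Protein-level and isoform-level results for every protein.

    ``group_labels`` maps the channel columns (in order) to two groups;
    folds and one-tailed p-values compare group1 vs group2.  Isoform
    assessability requires >=2 peptides.  Raw p-values are reported
    (mirroring supplementary-table convention); optional
    Benjamini-Hochberg columns are appended for convenience.
    """
    channels = channel_columns(proteins)
    labels = np.asarray(group_labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("differential table requires exactly two groups")
    pep_channels = channel_columns(peptides)
    rows = []
    for _, prow in proteins.iterrows():
        acc = prow["protein"]
        vals = prow[channels].to_numpy(dtype=float)
        p_prot, fold = protein_level_test(
            vals[labels == groups[0]], vals[labels == groups[1]],
            direction=direction,
        )
        sub = peptides[
            peptides["protein"].str.split(";").apply(lambda a: acc in a)
        ]
        mat = sub.set_index("peptide")[pep_channels]
        if len(mat) >= 2:
            iso = isoform_level_test(mat, labels)
        else:
            iso = IsoformTestResult(
                float("nan"), float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), float("nan"), assessable=False,
            )
        rows.append({
            "protein": acc,
            "gene": prow.get("gene", acc),
            "mean_fold": fold,
            "p_protein": p_prot,
            "p_genotype": iso.p_genotype,
            "p_peptide": iso.p_peptide,
            "p_interaction": iso.p_interaction,
            "isoform_assessable": iso.assessable,
            "is_protein_divergent": p_prot < alpha,
            "is_isoform_divergent": iso.is_isoform_divergent(alpha),
        })
    out = pd.DataFrame(rows)
    if with_bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_protein"] = multipletests(
            out["p_protein"].fillna(1.0), method="fdr_bh")[1]
        assess = out["isoform_assessable"]
        q = pd.Series(np.nan, index=out.index)
        if assess.any():
            q.loc[assess] = multipletests(
                out.loc[assess, "p_interaction"], method="fdr_bh")[1]
        out["q_interaction"] = q
    return out
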