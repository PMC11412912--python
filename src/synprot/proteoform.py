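"""Proteoform fingerprinting from peptide-level evidence.

A multi-isoform gene is represented as an ordered chain of exons, each
carrying an in-frame amino-acid segment.  Isoforms are ordered exon
subsets, optionally prefixed by an alternative N-terminal segment
contributed by an alternatively spliced transcript (AST).  Fully tryptic
peptides are mapped back to the exon (or exon junction) that encodes
them, and the normalized count profile over exons and junctions — the
exon detection-frequency table — serves as a fingerprint that can be
matched against the theoretical fingerprint of each candidate isoform.

Gel-slice molecular-weight gating restricts which isoforms are eligible
in a given SDS-PAGE slice before matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Average residue (monomer) masses in Da; adding one water gives the
# neutral average molecular weight of the intact chain.
AVERAGE_RESIDUE_MASS_DA: Mapping[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS_DA = 18.0153

JUNCTION_SEP = " & "


@dataclass(frozen=True)
class Exon:
    """One exon with its in-frame amino-acid segment."""

    id: str
    segment: str


@dataclass(frozen=True)
class Isoform:
    """An isoform: ordered exon-id list, optional alternative N-terminal
    segment (AST), and a flag set when a required exon was deleted."""

    name: str
    exon_ids: tuple[str, ...]
    alt_start: str | None = None
    untranslatable: bool = False


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    exons: tuple[Exon, ...]
    isoforms: tuple[Isoform, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate exon ids in gene {self.gene_id}")
        order = {eid: i for i, eid in enumerate(ids)}
        for iso in self.isoforms:
            missing = [e for e in iso.exon_ids if e not in order]
            if missing and not iso.untranslatable:
                raise ValueError(
                    f"isoform {iso.name} references unknown exons {missing}")
            pos = [order[e] for e in iso.exon_ids if e in order]
            if pos != sorted(pos):
                raise ValueError(f"isoform {iso.name} exon list not ordered")

    @property
    def exon_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.exons)

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == exon_id:
                return e
        raise KeyError(exon_id)

    def isoform(self, name: str) -> Isoform:
        for iso in self.isoforms:
            if iso.name == name:
                return iso
        raise KeyError(name)

    def to_json(self) -> str:
        obj = {
            "gene_id": self.gene_id,
            "exons": [{"id": e.id, "segment": e.segment} for e in self.exons],
            "isoforms": [
                {
                    "name": i.name,
                    "exon_ids": list(i.exon_ids),
                    "alt_start": i.alt_start,
                    "untranslatable": i.untranslatable,
                }
                for i in self.isoforms
            ],
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        obj = json.loads(text)
        return cls(
            gene_id=obj["gene_id"],
            exons=tuple(Exon(e["id"], e["segment"]) for e in obj["exons"]),
            isoforms=tuple(
                Isoform(
                    name=i["name"],
                    exon_ids=tuple(i["exon_ids"]),
                    alt_start=i.get("alt_start"),
                    untranslatable=bool(i.get("untranslatable", False)),
                )
                for i in obj["isoforms"]
            ),
        )


@dataclass(frozen=True)
class TrypticPeptide:
    """A fully tryptic peptide with 1-based inclusive coordinates on its
    parent isoform sequence and, once mapped, an exon/junction label."""

    sequence: str
    start: int
    end: int
    exon_label: str | None = None


@dataclass(frozen=True)
class GelSlice:
    """A gel slice defined by its molecular-weight window in kDa."""

    label: str
    mw_low_kda: float
    mw_high_kda: float

    def __post_init__(self) -> None:
        if not self.mw_low_kda < self.mw_high_kda:
            raise ValueError("gel slice window must have lower < upper")

    def contains(self, mw_kda: float) -> bool:
        return self.mw_low_kda <= mw_kda <= self.mw_high_kda


@dataclass
class ExonFrequencyTable:
    """Detection counts and frequencies per exon/AST label and per
    junction label.  Frequencies share one denominator (total detection
    events over exons, ASTs and junctions) and sum to 1."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()}

    @property
    def exon_labels(self) -> list[str]:
        return [k for k in self.counts if JUNCTION_SEP not in k]

    @property
    def junction_labels(self) -> list[str]:
        return [k for k in self.counts if JUNCTION_SEP in k]

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "label": list(self.counts),
                "kind": ["junction" if JUNCTION_SEP in k else "exon"
                         for k in self.counts],
                "count": list(self.counts.values()),
                "frequency": [freqs[k] for k in self.counts],
            }
        )


def _check_sequence(sequence: str) -> None:
    for pos, ch in enumerate(sequence, start=1):
        if ch not in AVERAGE_RESIDUE_MASS_DA:
            raise ValueError(
                f"illegal amino-acid character {ch!r} at position {pos}")


def cleave_fragments(sequence: str, exclude_proline: bool = False
                     ) -> list[TrypticPeptide]:
    """All zero-missed-cleavage tryptic fragments, unfiltered.

    Cleaves C-terminal to K/R; with ``exclude_proline`` the bond is kept
    when the next residue is proline.  Concatenating the fragment
    sequences reconstructs the input exactly.
    """
    _check_sequence(sequence)
    cuts = []
    for i, ch in enumerate(sequence):
        if ch in "KR" and i + 1 < len(sequence):
            if exclude_proline and sequence[i + 1] == "P":
                continue
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(sequence)]
    return [
        TrypticPeptide(sequence[a:b], a + 1, b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def digest_trypsin(sequence: str, min_len: int = 8, max_len: int = 35,
                   exclude_proline: bool = False) -> list[TrypticPeptide]:
    """Fully tryptic peptides of retained length (8-35 aa by default).

    Only zero-missed-cleavage peptides are produced; peptides shorter
    than ``min_len`` or longer than ``max_len`` are discarded, matching
    the length window outside which peptides are not observed in
    practice.
    """
    return [
        p for p in cleave_fragments(sequence, exclude_proline)
        if min_len <= len(p.sequence) <= max_len
    ]


def translate_isoform(model: GeneModel, isoform_name: str
                      ) -> tuple[str, list[str]]:
    """Protein sequence of an isoform plus the per-residue exon label.

    The alternative N-terminal segment, when present, comes first and
    its residues are labeled ``AST:<isoform>``.
    """
    iso = model.isoform(isoform_name)
    if iso.untranslatable:
        raise ValueError(
            f"isoform {isoform_name} of gene {model.gene_id} is "
            "untranslatable (a required exon was deleted)")
    seq_parts: list[str] = []
    labels: list[str] = []
    if iso.alt_start:
        seq_parts.append(iso.alt_start)
        labels.extend([f"AST:{iso.name}"] * len(iso.alt_start))
    for eid in iso.exon_ids:
        seg = model.exon(eid).segment
        seq_parts.append(seg)
        labels.extend([eid] * len(seg))
    return "".join(seq_parts), labels


def map_peptide_to_exons(peptide: TrypticPeptide,
                         residue_map: Sequence[str]) -> str:
    """Exon label of a peptide: the single exon covering it, or a
    junction label "A & B" when it spans adjacent exons (chained for
    three or more)."""
    if peptide.start < 1 or peptide.end > len(residue_map):
        raise ValueError(
            f"peptide coordinates {peptide.start}-{peptide.end} outside "
            f"isoform of length {len(residue_map)}")
    seen: list[str] = []
    for label in residue_map[peptide.start - 1:peptide.end]:
        if not seen or seen[-1] != label:
            seen.append(label)
    return JUNCTION_SEP.join(seen)


def theoretical_mw(sequence: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    _check_sequence(sequence)
    da = sum(AVERAGE_RESIDUE_MASS_DA[ch] for ch in sequence) + WATER_MASS_DA
    return da / 1000.0


def isoform_mw(model: GeneModel, isoform_name: str) -> float:
    seq, _ = translate_isoform(model, isoform_name)
    return theoretical_mw(seq)


def filter_isoforms_by_slice(model: GeneModel, gel_slice: GelSlice
                             ) -> list[str]:
    """Isoform names whose theoretical MW falls inside the slice window."""
    out = []
    for iso in model.isoforms:
        if iso.untranslatable:
            continue
        if gel_slice.contains(isoform_mw(model, iso.name)):
            out.append(iso.name)
    return out


def digest_isoform(model: GeneModel, isoform_name: str,
                   min_len: int = 8, max_len: int = 35,
                   exclude_proline: bool = False) -> list[TrypticPeptide]:
    """Retained tryptic peptides of one isoform, each labeled with its
    exon / junction / AST label."""
    seq, residue_map = translate_isoform(model, isoform_name)
    peptides = digest_trypsin(seq, min_len, max_len, exclude_proline)
    return [
        replace(p, exon_label=map_peptide_to_exons(p, residue_map))
        for p in peptides
    ]


def exon_frequency_table(detected: Iterable[TrypticPeptide | str]
                         ) -> ExonFrequencyTable:
    """Detection-frequency table from labeled peptides.

    Each peptide occurrence is one detection event for its exon (or AST,
    or junction) label; the frequency of every label is its event count
    divided by the total event count over all labels, so frequencies
    sum to 1.
    """
    counts: dict[str, int] = {}
    n = 0
    for item in detected:
        label = item if isinstance(item, str) else item.exon_label
        if label is None:
            raise ValueError("detected peptide lacks an exon label")
        counts[label] = counts.get(label, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("no detection events supplied")
    return ExonFrequencyTable(counts=counts)


def standard_tables(model: GeneModel, min_len: int = 8, max_len: int = 35,
                    exclude_proline: bool = False
                    ) -> dict[str, ExonFrequencyTable]:
    """Theoretical ("standard") frequency table per translatable isoform,
    counting each retained theoretical peptide once."""
    out: dict[str, ExonFrequencyTable] = {}
    for iso in model.isoforms:
        if iso.untranslatable:
            continue
        peptides = digest_isoform(model, iso.name, min_len, max_len,
                                  exclude_proline)
        if peptides:
            out[iso.name] = exon_frequency_table(peptides)
    return out


def _union_vectors(tables: Sequence[ExonFrequencyTable]
                   ) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    for t in tables:
        for k in t.counts:
            if k not in labels:
                labels.append(k)
    labels.sort()
    mat = np.zeros((len(tables), len(labels)))
    for i, t in enumerate(tables):
        freqs = t.frequencies
        for j, lab in enumerate(labels):
            mat[i, j] = freqs.get(lab, 0.0)
    return labels, mat


@dataclass
class IsoformAssignment:
    """Ranked isoform candidates for one observed fingerprint."""

    ranking: list[tuple[str, float]]
    embedding: pd.DataFrame | None = None

    @property
    def best(self) -> str:
        return self.ranking[0][0]


def assign_isoform(observed: ExonFrequencyTable,
                   standards: Mapping[str, ExonFrequencyTable],
                   method: str = "distance",
                   seed: int = 0) -> IsoformAssignment:
    """Match an observed fingerprint against per-isoform standards.

    Standards are ranked by Euclidean distance between union-aligned
    frequency vectors (missing labels are zero-filled); ties break
    lexicographically on the isoform name, so the ranking is fully
    deterministic.  With ``method="embedding"`` a t-SNE 2-D layout of
    the observed table plus all standards is attached for visualization;
    the assignment itself is always taken from the distance ranking.
    """
    if not standards:
        raise ValueError("no standard tables supplied")
    if method not in ("distance", "embedding"):
        raise ValueError(f"unknown method {method!r}")
    names = sorted(standards)
    _, mat = _union_vectors([observed] + [standards[n] for n in names])
    obs_vec, std_mat = mat[0], mat[1:]
    dists = np.sqrt(((std_mat - obs_vec) ** 2).sum(axis=1))
    ranking = sorted(zip(names, dists), key=lambda t: (t[1], t[0]))

    embedding = None
    if method == "embedding":
        from sklearn.manifold import TSNE

        n = mat.shape[0]
        perplexity = min(5.0, n - 1.0)
        coords = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed,
            init="pca",
        ).fit_transform(mat)
        embedding = pd.DataFrame(
            coords, columns=["tsne1", "tsne2"],
            index=["observed"] + names,
        )
    return IsoformAssignment(ranking=ranking, embedding=embedding)
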