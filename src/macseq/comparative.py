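"""Cross-individual SNV comparisons on a shared reference.

A :class:`GenotypePanel` holds per-site genotype classes (hom_ref, het,
hom_alt, missing) and alternate alleles for several individuals mapped
to the same reference, each labelled with a species group.  On top of it
sit the set operations used to compare genomes: shared and private SNVs,
merged unions, completely differentiated sites between species groups,
heterozygous-sharing fractions (an introgression signal), and a
category-restricted candidate-gene screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "shared_snvs", "merged_union", "private_snvs",
           "completely_differentiated", "shared_het_fraction", "gene_screen"]

_NON_REF = ("het", "hom_alt")


@dataclass
class GenotypePanel:
    """Sites x individuals genotype matrix.

    ``sites`` has columns chrom, pos plus ``gt_<ind>`` (genotype class)
    and ``alt_<ind>`` (alternate allele or None) per individual.
    ``groups`` maps individual name -> species-group label.
    """

    sites: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("panel needs at least one labelled individual")
        for ind in self.groups:
            for col in (f"gt_{ind}", f"alt_{ind}"):
                if col not in self.sites.columns:
                    raise ValueError(f"missing column {col!r}")
        if any(not g for g in self.groups.values()):
            raise ValueError("group labels must be non-empty")

    @property
    def individuals(self) -> list[str]:
        return list(self.groups)

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == group]

    def gt(self, ind: str) -> np.ndarray:
        return self.sites[f"gt_{ind}"].to_numpy()

    def alt(self, ind: str) -> np.ndarray:
        return self.sites[f"alt_{ind}"].to_numpy()

    def key(self) -> pd.DataFrame:
        return self.sites[["chrom", "pos"]]

    @classmethod
    def from_calls(cls, calls_by_individual: dict[str, pd.DataFrame],
                   groups: dict[str, str]) -> "GenotypePanel":
        """Assemble a panel from per-individual variant-call tables.

        The site list is the union of all variant sites; an individual
        without a record at a site is taken as hom_ref there (the panel
        assumes jointly callable genomes; use explicit ``missing`` rows
        to mark uncallable sites).
        """
        keys = pd.concat([c[["chrom", "pos"]] for c in calls_by_individual.values()])
        sites = keys.drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True)
        for ind, calls in calls_by_individual.items():
            zyg = calls["zygosity"].replace({"hom": "hom_alt"})
            sub = pd.DataFrame({
                "chrom": calls["chrom"], "pos": calls["pos"],
                f"gt_{ind}": zyg, f"alt_{ind}": calls["alt"]})
            sites = sites.merge(sub, on=["chrom", "pos"], how="left")
            sites[f"gt_{ind}"] = sites[f"gt_{ind}"].fillna("hom_ref")
            sites[f"alt_{ind}"] = sites[f"alt_{ind}"].where(
                sites[f"alt_{ind}"].notna(), None)
        return cls(sites, dict(groups))


def _select(panel: GenotypePanel, mask: np.ndarray) -> pd.DataFrame:
    return panel.key()[mask].reset_index(drop=True)


def shared_snvs(panel: GenotypePanel, a: str, b: str) -> pd.DataFrame:
    """Sites where both individuals carry the *same* alternate allele in
    any non-reference genotype (het or hom)."""
    ga, gb = panel.gt(a), panel.gt(b)
    mask = (np.isin(ga, _NON_REF) & np.isin(gb, _NON_REF)
            & (panel.alt(a) == panel.alt(b)))
    return _select(panel, mask)


def merged_union(panel: GenotypePanel, a: str, b: str) -> pd.DataFrame:
    """Union of the two individuals' non-reference sites."""
    mask = np.isin(panel.gt(a), _NON_REF) | np.isin(panel.gt(b), _NON_REF)
    return _select(panel, mask)


def private_snvs(panel: GenotypePanel, a: str) -> pd.DataFrame:
    """Non-reference sites of ``a`` where every other panel member is
    confidently hom_ref.

    Sites where any other individual is missing are dropped: absence of
    evidence there cannot establish privacy.
    """
    if a not in panel.groups:
        raise ValueError(f"{a!r} not in panel")
    mask = np.isin(panel.gt(a), _NON_REF)
    for other in panel.individuals:
        if other == a:
            continue
        mask &= panel.gt(other) == "hom_ref"
    return _select(panel, mask)


def completely_differentiated(panel: GenotypePanel, group1: str, group2: str,
                              allow_het: bool = False) -> pd.DataFrame:
    """Sites fixed for different alleles in the two species groups.

    Strict reading: every member of both groups homozygous (no hets
    unless ``allow_het``, no missing), all group-1 members carrying one
    allele and all group-2 members the other.
    """
    m1, m2 = panel.members(group1), panel.members(group2)
    if not m1 or not m2 or set(m1) & set(m2):
        raise ValueError("groups must be disjoint and non-empty")

    n = len(panel.sites)

    def group_allele(members: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(valid, allele) where allele is the shared hom allele per site."""
        valid = np.ones(n, dtype=bool)
        allele = np.full(n, None, dtype=object)
        first = True
        for ind in members:
            gt = panel.gt(ind)
            if allow_het:
                ok = np.isin(gt, ("hom_ref", "hom_alt", "het"))
            else:
                ok = np.isin(gt, ("hom_ref", "hom_alt"))
            valid &= ok
            this = np.where(gt == "hom_ref", "<REF>", panel.alt(ind))
            if first:
                allele = this
                first = False
            else:
                valid &= allele == this
        return valid, allele

    v1, a1 = group_allele(m1)
    v2, a2 = group_allele(m2)
    mask = v1 & v2 & (a1 != a2)
    return _select(panel, mask)


def shared_het_fraction(panel: GenotypePanel, a: str, b: str) -> float:
    """Fraction of a's heterozygous SNVs that are also heterozygous in b
    with the same alternate allele."""
    ha = panel.gt(a) == "het"
    if not ha.any():
        raise ZeroDivisionError(f"{a!r} has no heterozygous sites")
    both = ha & (panel.gt(b) == "het") & (panel.alt(a) == panel.alt(b))
    return float(both.sum() / ha.sum())


def gene_screen(effects: pd.DataFrame, differentiated: pd.DataFrame,
                gene_category_map: pd.DataFrame,
                warn=None) -> pd.DataFrame:
    """Category-restricted screen for differentiated amino-acid variants.

    Returns one row per (category, gene) with the count of qualifying
    SNVs: nonsynonymous, homozygous in the focal individual, and lying
    in the ``differentiated`` site set.  ``effects`` needs chrom, pos,
    gene_id, coding_effect, zygosity; ``gene_category_map`` needs
    gene_id, category.  Unknown gene names in the map are ignored (and
    reported through ``warn`` if given).
    """
    known = set(effects["gene_id"].dropna())
    unknown = sorted(set(gene_category_map["gene_id"]) - known)
    if unknown and warn is not None:
        warn(f"{len(unknown)} mapped gene(s) absent from effects: {unknown[:5]}")
    diff_keys = set(zip(differentiated["chrom"], differentiated["pos"]))
    in_diff = np.fromiter((k in diff_keys for k in
                           zip(effects["chrom"], effects["pos"])),
                          dtype=bool, count=len(effects))
    e = effects[
        effects["coding_effect"].isin(("nonsynonymous", "nonsense")).to_numpy()
        & effects["zygosity"].isin(("hom", "hom_alt")).to_numpy()
        & in_diff
    ]
    merged = e.merge(gene_category_map, on="gene_id", how="inner")
    out = (merged.groupby(["category", "gene_id"])
           .size().rename("n_snvs").reset_index()
           .sort_values(["category", "gene_id"]).reset_index(drop=True))
    return out
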