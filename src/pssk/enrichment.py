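"""Phosphoproteome statistics: dynamic sites, IDR enrichment, motifs.

The pipeline mirrors a standard label-free phosphoproteomics workflow:

1. log2 intensities, median-normalised per sample;
2. left-censored missing values imputed from a down-shifted normal
   (downshift 1.8 sd of the whole dataset, width 0.3 sd);
3. per-site one-way ANOVA across time-point groups, Benjamini-Hochberg
   FDR < 0.05 defining the "dynamic" sites;
4. enrichment of phosphorylation in disordered regions corrected for the
   compositional bias of S/T/P-rich IDRs: per-protein expected versus
   observed phospho-S/T in the IDR with a one-sided binomial test, and a
   pooled 2x2 odds ratio (Fisher exact; a stratified Mantel-Haenszel
   variant behind a flag);
5. per-amino-acid differential disorder composition
   (comp_disorder - comp_phosphoproteome) / comp_phosphoproteome;
6. kinase consensus-motif classification of sites;
7. group comparisons of disorder fractions (Mann-Whitney for two groups,
   Kruskal-Wallis plus Dunn's BH-adjusted post hocs beyond that).

Site tables are pandas DataFrames with columns
``protein_id, position, residue, phosphorylated, in_idr`` (and optionally
``dynamic``); positions are 1-based. Tyrosine rows are excluded from all
IDR-enrichment denominators, which are defined on Ser/Thr only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sequences import AA_ALPHABET, AminoAcidSequence

HYDROPHOBIC = set("AVILMFWY")

SITE_COLUMNS = ("protein_id", "position", "residue", "phosphorylated",
                "in_idr")


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    bad = set(sites["residue"]) - set("STY")
    if bad:
        raise ValueError(f"site table holds non-S/T/Y residues {sorted(bad)}")
    return sites


# ---------------------------------------------------------------------------
# Intensity matrices

@dataclass
class IntensityMatrix:
    """sites x samples log2 intensities with a sample -> group mapping."""

    data: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self):
        unknown = set(self.data.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without a group: {sorted(unknown)}")

    def group_arrays(self, row: pd.Series) -> list[np.ndarray]:
        cols = pd.Index(self.data.columns)
        out = []
        for g in sorted(set(self.groups.values())):
            members = [c for c in cols if self.groups[c] == g]
            out.append(row[members].to_numpy(dtype=float))
        return out


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract each sample's median (computed over finite entries)."""
    data = matrix.data - matrix.data.median(axis=0, skipna=True)
    return IntensityMatrix(data, dict(matrix.groups))


def impute_missing(matrix: IntensityMatrix, downshift: float = 1.8,
                   width: float = 0.3, seed: int = 0) -> IntensityMatrix:
    """Replace missing entries with draws from a down-shifted normal.

    The replacement distribution is Normal(mean - downshift * sd,
    (width * sd)^2) with mean and sd taken over ALL finite values of the
    matrix — the standard left-censoring imputation for intensities that
    fell below the detection limit.
    """
    values = matrix.data.to_numpy(dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite intensities to impute")
    mean, sd = values[finite].mean(), values[finite].std(ddof=1)
    rng = np.random.default_rng(seed)
    out = values.copy()
    n_missing = (~finite).sum()
    out[~finite] = rng.normal(mean - downshift * sd, width * sd,
                              size=n_missing)
    return IntensityMatrix(pd.DataFrame(out, index=matrix.data.index,
                                        columns=matrix.data.columns),
                           dict(matrix.groups))


def classify_dynamic_sites(matrix: IntensityMatrix, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """One-way ANOVA per site across groups, BH-adjusted across sites.

    Returns a frame indexed like the matrix with columns F, p, q, dynamic.
    Degenerate sites (zero variance within every group) are skipped with a
    warning and carry NaN statistics / dynamic = False.
    """
    group_labels = sorted(set(matrix.groups.values()))
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    members = {g: [c for c in matrix.data.columns if matrix.groups[c] == g]
               for g in group_labels}
    for g, cols in members.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    F = np.full(len(matrix.data), np.nan)
    p = np.full(len(matrix.data), np.nan)
    skipped = 0
    for i, (_, row) in enumerate(matrix.data.iterrows()):
        arrays = [row[cols].to_numpy(dtype=float) for cols in members.values()]
        if all(np.allclose(a, a[0]) for a in arrays) and \
                np.allclose(np.concatenate(arrays),
                            np.concatenate(arrays)[0]):
            skipped += 1
            continue
        F[i], p[i] = stats.f_oneway(*arrays)
    if skipped:
        warnings.warn(f"{skipped} degenerate site(s) skipped "
                      "(zero variance across all groups)")
    q = np.full_like(p, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return pd.DataFrame({"F": F, "p": p, "q": q,
                         "dynamic": np.where(np.isfinite(q), q < alpha,
                                             False).astype(bool)},
                        index=matrix.data.index)


# ---------------------------------------------------------------------------
# IDR enrichment

@dataclass(frozen=True)
class ContingencyTable:
    """Pooled phospho x IDR counts over Ser/Thr residues.

    a: phospho in IDR; b: phospho in structured;
    c: non-phospho S/T in IDR; d: non-phospho S/T in structured.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_sites(cls, sites: pd.DataFrame) -> "ContingencyTable":
        s = validate_site_table(sites)
        st = s[s.residue.isin(("S", "T"))]
        return cls(
            int((st.phosphorylated & st.in_idr).sum()),
            int((st.phosphorylated & ~st.in_idr).sum()),
            int((~st.phosphorylated & st.in_idr).sum()),
            int((~st.phosphorylated & ~st.in_idr).sum()),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    haldane_corrected: bool = False

    def summary(self) -> str:
        note = " (Haldane-Anscombe 0.5 correction)" if self.haldane_corrected \
            else ""
        return (f"OR = {self.odds_ratio:.4g} "
                f"[95% CI {self.ci_low:.4g}, {self.ci_high:.4g}], "
                f"p = {self.p_value:.3g} ({self.method}){note}")


def pooled_odds_ratio(sites: pd.DataFrame | ContingencyTable,
                      stratify_by_protein: bool = False) -> OddsRatioResult:
    """Odds ratio of S/T phosphorylation in IDRs vs structured regions.

    Default: Fisher exact test on the pooled 2x2 table, with a 95% CI from
    the normal approximation on the log odds ratio (the reported method).
    ``stratify_by_protein`` switches to the Mantel-Haenszel common odds
    ratio across per-protein 2x2 strata.
    """
    if stratify_by_protein:
        if isinstance(sites, ContingencyTable):
            raise ValueError("stratified estimate needs the full site table")
        from statsmodels.stats.contingency_tables import StratifiedTable
        tables = []
        for _, grp in validate_site_table(sites).groupby("protein_id"):
            ct = ContingencyTable.from_sites(grp)
            tables.append(np.array([[ct.a, ct.b], [ct.c, ct.d]], float))
        st = StratifiedTable(tables)
        or_mh = float(st.oddsratio_pooled)
        ci = st.oddsratio_pooled_confint(alpha=0.05)
        p = float(st.test_null_odds().pvalue)
        return OddsRatioResult(or_mh, float(ci[0]), float(ci[1]), p,
                               "Mantel-Haenszel (stratified by protein)")
    ct = sites if isinstance(sites, ContingencyTable) \
        else ContingencyTable.from_sites(sites)
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = (math.exp(math.log(oratio) - z * se),
              math.exp(math.log(oratio) + z * se))
    return OddsRatioResult(float(oratio), lo, hi, float(p),
                           "Fisher exact; log-OR normal-approximation CI",
                           corrected)


def expected_observed_idr(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-protein expected vs observed phospho-S/T in the IDR.

    Expected = n_phospho * (S/T in IDR) / (S/T total); the observed count
    is tested against that proportion with a one-sided (greater) binomial
    test, BH-adjusted across proteins. Proteins without any S/T or any
    phosphosite are excluded (they carry no information for this test).
    """
    s = validate_site_table(sites)
    st = s[s.residue.isin(("S", "T"))]
    rows = []
    for pid, grp in st.groupby("protein_id"):
        n_st = len(grp)
        n_idr = int(grp.in_idr.sum())
        n_ph = int(grp.phosphorylated.sum())
        if n_st == 0 or n_ph == 0:
            continue
        prop = n_idr / n_st
        observed = int((grp.phosphorylated & grp.in_idr).sum())
        pval = stats.binomtest(observed, n_ph, prop,
                               alternative="greater").pvalue
        rows.append((pid, n_ph * prop, observed, n_ph, prop, pval))
    out = pd.DataFrame(rows, columns=["protein_id", "expected", "observed",
                                      "n_phospho", "idr_st_proportion", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out


def differential_composition(disorder_seqs: Sequence[str],
                             phosphoproteome_seqs: Sequence[str]
                             ) -> pd.DataFrame:
    """(comp_disorder - comp_phosphoproteome) / comp_phosphoproteome per
    amino acid; positive values mark residues enriched in disorder.

    Residues absent from the phosphoproteome give an undefined (NaN)
    delta, reported as such rather than dropped.
    """
    def comp(seqs):
        joined = "".join(s.residues if isinstance(s, AminoAcidSequence)
                         else s for s in seqs)
        if not joined:
            raise ValueError("empty sequence set")
        counts = pd.Series(list(joined)).value_counts()
        return np.array([counts.get(a, 0) / len(joined) for a in AA_ALPHABET])

    cd, cp = comp(disorder_seqs), comp(phosphoproteome_seqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(cp > 0, (cd - cp) / np.where(cp > 0, cp, 1), np.nan)
    return pd.DataFrame({"amino_acid": list(AA_ALPHABET),
                         "comp_disorder": cd,
                         "comp_phosphoproteome": cp,
                         "delta": delta})


# ---------------------------------------------------------------------------
# Kinase consensus motifs

def _res(seq: AminoAcidSequence, pos: int) -> str | None:
    """Residue at 1-based pos, or None out of range (rule fails to match)."""
    if 1 <= pos <= len(seq):
        return seq.residues[pos - 1]
    return None


def classify_motifs(seq: AminoAcidSequence, position: int) -> set[str]:
    """Kinase consensus labels matching a phosphosite.

    The phosphoacceptor itself must be S or T; rules needing sequence
    context beyond either end simply do not match. A site may carry any
    number of labels; the full CDK consensus implies the minimal one.
    """
    p = position
    site = seq.residue(p)
    if site not in "ST":
        raise ValueError(f"position {p} holds {site}, not S/T")
    r = lambda off: _res(seq, p + off)
    labels: set[str] = set()

    def is_in(off, allowed) -> bool:
        v = r(off)
        return v is not None and v in allowed

    if is_in(-2, "DNEY") and r(-1) is not None and is_in(+1, HYDROPHOBIC):
        labels.add("PLK")
    if is_in(-2, "KR") and r(-1) is not None and r(+1) is not None \
            and r(+1) != "P":
        labels.add("Aurora")
    if is_in(-2, "LMFW") and r(-1) is not None \
            and is_in(+1, "AVILFWYM") and is_in(+2, "KR"):
        labels.add("NEK")
    if (is_in(-5, "DE") and is_in(-4, "DE") and is_in(-3, "DE")) \
            or is_in(-3, "ST"):
        labels.add("CK1")
    if is_in(-1, "ST") and r(+1) is not None and is_in(+2, "EDS"):
        labels.add("CK2")
    if (is_in(+1, "ED") and r(+2) is not None and is_in(+3, "ED")) \
            or (is_in(+1, "ST") and r(+2) == "P"):
        labels.add("DDK")
    if r(-3) == "R" and is_in(-2, "RK") and r(-1) is not None \
            and is_in(+1, HYDROPHOBIC):
        labels.add("PKA")
    if r(+1) == "P":
        labels.add("CDK_minimal")
        if r(+2) is not None and is_in(+3, "KR"):
            labels.add("CDK_full")
        if r(-2) == "P":
            labels.add("MAPK")
    return labels


def classify_motifs_table(seq: AminoAcidSequence,
                          positions: Sequence[int]) -> pd.DataFrame:
    rows = [(seq.id, p, seq.residue(p),
             ";".join(sorted(classify_motifs(seq, p)))) for p in positions]
    return pd.DataFrame(rows, columns=["protein_id", "position", "residue",
                                       "motifs"])


# ---------------------------------------------------------------------------
# Group comparisons of disorder fractions

@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None   # Dunn post hocs, BH-adjusted

    def summary(self) -> str:
        out = f"{self.test}: statistic = {self.statistic:.4g}, " \
              f"p = {self.p_value:.3g}"
        if self.pairwise is not None:
            out += "\n" + self.pairwise.to_string(index=False)
        return out


def _dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction, BH-adjusted."""
    labels = sorted(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank, i0 = {}, 0
    for g in labels:
        mean_rank[g] = ranks[i0:i0 + sizes[g]].mean()
        i0 += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n - 1.0)))
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            se = math.sqrt((n * (n + 1) / 12.0 - tie_term)
                           * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_rank[g1] - mean_rank[g2]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((g1, g2, z, p))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def disorder_fraction_compare(groups: Mapping[str, Sequence[float]]
                              ) -> GroupComparison:
    """Rank-based comparison of disorder fractions between groups.

    Two groups: two-sided Mann-Whitney U. More: Kruskal-Wallis, followed
    by Dunn's two-sided pairwise post hocs with BH adjustment.
    """
    groups = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has n < 3")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        (a, b) = groups.values()
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("Mann-Whitney U (two-sided)", float(u),
                               float(p))
    h, p = stats.kruskal(*groups.values())
    return GroupComparison("Kruskal-Wallis", float(h), float(p),
                           _dunn_posthoc(groups))
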