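"""Phosphoproteome statistics: imputation, ANOVA, enrichment, motifs."""

import math
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pssk.enrichment import (ContingencyTable, IntensityMatrix,
                             classify_dynamic_sites, classify_motifs,
                             differential_composition,
                             disorder_fraction_compare, expected_observed_idr,
                             impute_missing, median_normalize,
                             pooled_odds_ratio)
from pssk.sequences import AminoAcidSequence
from pssk.synth import SyntheticProteomeSpec, synth_proteome


def matrix(data, n_groups=2):
    df = pd.DataFrame(data)
    groups = {c: f"g{i % n_groups}" for i, c in enumerate(df.columns)}
    return IntensityMatrix(df, groups)


class TestImputation:
    def test_no_missing_is_identity(self, rng):
        m = matrix(rng.normal(20, 2, size=(50, 6)))
        out = impute_missing(m, seed=1)
        assert np.array_equal(out.data.values, m.data.values)

    def test_downshifted_normal_moments(self, rng):
        data = pd.DataFrame(rng.normal(20, 2, size=(2000, 6)))
        data.iloc[rng.random((2000, 6)) < 0.3] = np.nan
        m = matrix(data)
        mean = np.nanmean(data.values)
        sd = np.nanstd(data.values, ddof=1)
        out = impute_missing(m, seed=7)
        imp = out.data.values[np.isnan(data.values)]
        assert imp.mean() == pytest.approx(mean - 1.8 * sd, abs=0.05)
        assert imp.std() == pytest.approx(0.3 * sd, abs=0.05)

    def test_seed_reproducibility(self, rng):
        data = pd.DataFrame(rng.normal(20, 2, size=(100, 6)))
        data.iloc[rng.random((100, 6)) < 0.2] = np.nan
        m = matrix(data)
        a = impute_missing(m, seed=3).data
        b = impute_missing(m, seed=3).data
        assert a.equals(b)

    def test_all_missing_rejected(self):
        m = matrix(np.full((5, 4), np.nan))
        with pytest.raises(ValueError):
            impute_missing(m)


class TestMedianNormalise:
    def test_sample_medians_zeroed(self, rng):
        m = matrix(rng.normal(20, 3, size=(200, 6)))
        out = median_normalize(m)
        assert np.allclose(out.data.median(axis=0), 0.0)


class TestDynamicSites:
    def _planted(self, seed=0, nrep=4):
        # 4 groups x 4 replicates; a 4-sd shift of one group gives the
        # one-way ANOVA noncentrality ~48, enough for near-complete power
        rng = np.random.default_rng(seed)
        flat = rng.normal(20, 1, size=(100, 4 * nrep))
        shifted = rng.normal(20, 1, size=(100, 4 * nrep))
        shifted[:, 3 * nrep:] += 4.0
        df = pd.DataFrame(np.vstack([flat, shifted]))
        groups = {c: f"t{c // nrep}" for c in df.columns}
        return IntensityMatrix(df, groups)

    def test_power_and_specificity(self):
        report = classify_dynamic_sites(self._planted())
        planted = report.dynamic.values[100:]
        null = report.dynamic.values[:100]
        assert planted.sum() >= 95
        assert null.sum() <= 10

    def test_all_flat_finds_nothing(self, rng):
        base = rng.normal(20, 1, size=100)
        df = pd.DataFrame(np.tile(base[:, None], (1, 8)))
        df += rng.normal(0, 1e-9, size=df.shape)  # break exact degeneracy
        m = IntensityMatrix(df, {c: f"t{c // 2}" for c in df.columns})
        report = classify_dynamic_sites(m)
        assert report.dynamic.sum() == 0

    def test_within_group_label_permutation_invariance(self):
        m = self._planted()
        cols = list(m.data.columns)
        # swap replicates within each group: same grouping, new order
        perm = [c for pair in zip(cols[1::4], cols[0::4], cols[3::4],
                                  cols[2::4])
                for c in pair]
        m2 = IntensityMatrix(m.data[perm], {c: m.groups[c] for c in perm})
        a = classify_dynamic_sites(m)
        b = classify_dynamic_sites(m2)
        assert a.dynamic.equals(b.dynamic)

    def test_degenerate_sites_skipped_with_warning(self):
        df = pd.DataFrame(np.vstack([np.full(8, 5.0),
                                     np.random.default_rng(0).normal(size=8)]))
        m = IntensityMatrix(df, {c: f"t{c // 2}" for c in df.columns})
        with pytest.warns(UserWarning, match="degenerate"):
            report = classify_dynamic_sites(m)
        assert not report.dynamic.iloc[0]
        assert np.isnan(report.p.iloc[0])


def sites_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "position", "residue",
                                       "phosphorylated", "in_idr"])


class TestExpectedObserved:
    def test_expected_proportion(self):
        rows = []
        # 10 S/T, 4 in IDR; 5 phospho of which 3 in IDR
        for i in range(10):
            rows.append(("P1", i + 1, "S", i < 5, (i % 10) in (0, 1, 5, 6)))
        out = expected_observed_idr(sites_frame(rows))
        assert out.expected.iloc[0] == pytest.approx(5 * 4 / 10)
        assert out.observed.iloc[0] == 2  # positions 1,2 of the phospho five

    def test_binomial_tail_matches_manual_summation(self):
        rows = [("P1", i + 1, "T", i < 6, i % 3 == 0) for i in range(12)]
        out = expected_observed_idr(sites_frame(rows))
        n, prop = 6, 4 / 12
        obs = int(out.observed.iloc[0])
        manual = sum(math.comb(n, i) * prop ** i * (1 - prop) ** (n - i)
                     for i in range(obs, n + 1))
        assert out.p.iloc[0] == pytest.approx(manual, rel=1e-12)

    def test_observed_equal_expected_not_significant(self):
        # all S/T in the IDR: observed = expected, one-sided p = 1
        rows = [("P1", i + 1, "S", i < 3, True) for i in range(6)]
        out = expected_observed_idr(sites_frame(rows))
        assert out.p.iloc[0] == pytest.approx(1.0)

    def test_tyrosine_excluded(self):
        rows = [("P1", 1, "Y", True, True), ("P1", 2, "S", True, False),
                ("P1", 3, "S", False, False)]
        out = expected_observed_idr(sites_frame(rows))
        assert out.n_phospho.iloc[0] == 1


class TestOddsRatio:
    def test_symmetric_table(self):
        res = pooled_odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_worked_table(self):
        res = pooled_odds_ratio(ContingencyTable(20, 5, 10, 40))
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.ci_low < 16.0 < res.ci_high

    def test_transposed_roles_give_reciprocal(self):
        a = pooled_odds_ratio(ContingencyTable(20, 5, 10, 40))
        b = pooled_odds_ratio(ContingencyTable(5, 20, 40, 10))
        assert a.odds_ratio == pytest.approx(1.0 / b.odds_ratio)

    def test_zero_cell_haldane_flagged(self):
        res = pooled_odds_ratio(ContingencyTable(5, 0, 3, 7))
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)

    def test_fisher_p_matches_scipy_reference(self):
        res = pooled_odds_ratio(ContingencyTable(12, 7, 5, 21))
        _, p = stats.fisher_exact([[12, 7], [5, 21]])
        assert res.p_value == pytest.approx(p)

    def test_stratified_estimator_available(self):
        spec = SyntheticProteomeSpec(n_proteins=20, mean_length=200,
                                     odds_ratio=3.0, seed=1)
        sp = synth_proteome(spec, with_intensities=False)
        res = pooled_odds_ratio(sp.sites, stratify_by_protein=True)
        assert "Mantel-Haenszel" in res.method
        assert res.ci_low < res.odds_ratio < res.ci_high


class TestDifferentialComposition:
    def test_identical_sets_give_zero(self):
        out = differential_composition(["ASTGKR"], ["ASTGKR"])
        assert np.allclose(out.delta.dropna(), 0.0)

    def test_worked_delta(self):
        # P is 10% of the disorder set, 8% of the phosphoproteome
        dis = "P" + "A" * 9
        pho = "PP" + "A" * 23
        out = differential_composition([dis], [pho])
        assert out.set_index("amino_acid").delta["P"] == pytest.approx(0.25)

    def test_absent_from_disorder_gives_minus_one(self):
        out = differential_composition(["AAAA"], ["AAWW"])
        d = out.set_index("amino_acid").delta
        assert d["W"] == pytest.approx(-1.0)

    def test_absent_from_phosphoproteome_is_undefined(self):
        out = differential_composition(["AAWW"], ["AAAA"])
        assert np.isnan(out.set_index("amino_acid").delta["W"])


MOTIF_REGEXES = {
    # (pattern, 0-based offset of the phosphosite within the match)
    "PLK": (r"[DNEY].[ST][AVILMFWY]", 2),
    "Aurora": (r"[KR].[ST][^P]", 2),
    "NEK": (r"[LMFW].[ST][AVILFWYM][KR]", 2),
    "CK1a": (r"[DE][DE][DE]..[ST]", 5),
    "CK1b": (r"[ST]..[ST]", 3),
    "CK2": (r"[ST][ST].[EDS]", 1),
    "DDKa": (r"[ST][ED].[ED]", 0),
    "DDKb": (r"[ST][ST]P", 0),
    "PKA": (r"R[RK].[ST][AVILMFWY]", 3),
    "CDK_minimal": (r"[ST]P", 0),
    "CDK_full": (r"[ST]P.[KR]", 0),
    "MAPK": (r"P.[ST]P", 2),
}


_CANONICAL = {"CK1a": "CK1", "CK1b": "CK1", "DDKa": "DDK", "DDKb": "DDK"}


def regex_oracle(residues: str, position: int) -> set:
    """Independent regex route: overlapping matches via lookahead."""
    found = set()
    for label, (pat, off) in MOTIF_REGEXES.items():
        for m in re.finditer(f"(?=({pat}))", residues):
            if m.start() + off == position - 1:
                found.add(_CANONICAL.get(label, label))
    return found


class TestMotifs:
    def test_cdk_full_example(self):
        s = AminoAcidSequence("t", "AASPAKAA")
        labels = classify_motifs(s, 3)
        assert {"CDK_minimal", "CDK_full"} <= labels

    def test_no_context_no_labels(self):
        s = AminoAcidSequence("t", "AASAAAAA")
        assert classify_motifs(s, 3) == set()

    def test_cdk_full_implies_minimal(self, rng):
        seq = AminoAcidSequence("t", "".join(
            rng.choice(list("STPKRAGDE"), size=500)))
        for p in range(1, 501):
            if seq.residue(p) in "ST":
                labels = classify_motifs(seq, p)
                if "CDK_full" in labels:
                    assert "CDK_minimal" in labels

    def test_non_phosphoacceptor_rejected(self):
        with pytest.raises(ValueError):
            classify_motifs(AminoAcidSequence("t", "APA"), 1)

    def test_agrees_with_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(99)
        alphabet = list("STPKRDEAGNVLFWYMIQ")
        checked = 0
        while checked < 10_000:
            residues = "".join(rng.choice(alphabet, size=200))
            seq = AminoAcidSequence("t", residues)
            for p in range(1, 201):
                if residues[p - 1] in "ST":
                    assert classify_motifs(seq, p) == \
                        regex_oracle(residues, p), (residues, p)
                    checked += 1


class TestGroupComparisons:
    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=50)
        res = disorder_fraction_compare({"a": g, "b": g})
        assert res.p_value > 0.9

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(2, 1, 200)
        res = disorder_fraction_compare({"a": a, "b": b})
        assert res.p_value < 1e-3

    def test_three_equal_groups_no_dunn_hits(self, rng):
        g = {k: rng.normal(size=60) for k in "abc"}
        res = disorder_fraction_compare(g)
        assert res.test == "Kruskal-Wallis"
        assert (res.pairwise.q >= 0.05).all()

    def test_three_groups_one_shifted(self, rng):
        g = {"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100),
             "c": rng.normal(3, 1, 100)}
        res = disorder_fraction_compare(g)
        q = res.pairwise.set_index(["group1", "group2"]).q
        assert q[("a", "c")] < 0.01 and q[("b", "c")] < 0.01
        assert q[("a", "b")] > 0.05

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            disorder_fraction_compare({"a": [1.0], "b": [1, 2, 3]})
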