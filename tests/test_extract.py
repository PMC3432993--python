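"""Pattern extraction, categorization, and cross-tissue flagging."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

import toxsig as ts
from toxsig.extract import EPIGExtractor, ExtractionParams, categorize_genes, flag_coregulated, local_clusters
from toxsig.groups import GroupStructure
from toxsig.stats import correlation_cutoff, profile_stats

from conftest import expand_template


def make_groups(meta):
    return GroupStructure.from_metadata(meta)


class TestLocalClusters:
    def test_duplicated_rows_are_mutual_neighbors(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=12)
        X = np.vstack([row, row, rng.normal(size=12)])
        nbrs = local_clusters(X, r_star=0.9)
        assert 1 in nbrs[0] and 0 in nbrs[1]

    def test_negated_gene_is_not_a_neighbor(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=12)
        nbrs = local_clusters(np.vstack([row, -row]), r_star=0.5)
        assert nbrs[0].size == 0 and nbrs[1].size == 0

    def test_constant_profiles_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = np.vstack([np.zeros(12), rng.normal(size=12), rng.normal(size=12)])
        with pytest.warns(UserWarning, match="constant"):
            nbrs = local_clusters(X, r_star=0.1)
        assert nbrs[0].size == 0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        nbrs = local_clusters(X, r_star=0.3)
        for g, ns in enumerate(nbrs):
            for h in ns:
                assert g in nbrs[h]

    def test_planted_template_pairs_are_neighbors(self, training6, training6_extract):
        truth = training6["truth"].gene_template
        est = training6_extract["extractor"]
        X = ts.orient_forward(training6["expression"], training6["metadata"])
        keep = GroupStructure.column_mask(training6["metadata"])
        nbrs = local_clusters(X.to_numpy()[:, keep], est.r_star_)
        gene_ids = list(training6["expression"].index)
        idx_of = {g: i for i, g in enumerate(gene_ids)}
        tid = "down_both_dose"
        members = [idx_of[g] for g in truth.index[truth == tid]]
        hits = sum(
            (b in nbrs[a]) for i, a in enumerate(members) for b in members[i + 1:]
        )
        total = len(members) * (len(members) - 1) // 2
        assert hits / total >= 0.95


def naive_extract_membership(X, groups, params):
    """Brute-force reference: explicit loops and scipy correlations.

    Same contract as the estimator — SNR-ranked greedy seeding over
    correlation local clusters, most-correlated-pair merging, one
    reassignment against final representatives, profile gates — written
    independently with pairwise ``pearsonr`` calls and python sets.
    """
    n, m = X.shape
    st_ = profile_stats(X, groups)
    r_star = correlation_cutoff(params.p_threshold, m)
    merge_r = params.merge_r if params.merge_r is not None else r_star

    def r(u, v):
        if np.std(u) == 0 or np.std(v) == 0:
            return -np.inf
        return pearsonr(u, v)[0]

    corr = np.array([[r(X[i], X[j]) for j in range(n)] for i in range(n)])
    eligible = [
        g
        for g in range(n)
        if abs(st_.S[g]) > params.s_magnitude and abs(st_.SNR[g]) > params.snr_min
        and np.std(X[g]) > 0
    ]
    order = sorted(eligible, key=lambda g: -abs(st_.SNR[g]))
    covered, clusters = set(), []
    for g in order:
        if g in covered:
            continue
        members = {h for h in range(n) if corr[g, h] >= r_star and h not in covered}
        members.add(g)
        members -= covered
        if len(members) >= params.min_cluster_size:
            clusters.append(sorted(members))
            covered |= members
    # merge the most-correlated pair until none reaches merge_r
    while len(clusters) > 1:
        profs = [X[c].mean(axis=0) for c in clusters]
        best, bi, bj = -np.inf, None, None
        for i in range(len(profs)):
            for j in range(i + 1, len(profs)):
                rij = r(profs[i], profs[j])
                if rij > best:
                    best, bi, bj = rij, i, j
        if best < merge_r:
            break
        merged = sorted(set(clusters[bi]) | set(clusters[bj]))
        clusters = [c for k, c in enumerate(clusters) if k not in (bi, bj)] + [merged]
    # one reassignment against final representatives, then profile gates
    profs = [X[c].mean(axis=0) for c in clusters]
    members = [[] for _ in profs]
    for g in range(n):
        rs = [r(X[g], p) for p in profs]
        if not rs:
            break
        k = int(np.argmax(rs))
        if rs[k] >= r_star:
            members[k].append(g)
    final = []
    for mem in members:
        if not mem:
            continue
        prof = X[mem].mean(axis=0)
        pst = profile_stats(prof, groups)
        if abs(pst.S[0]) > params.s_magnitude and abs(pst.SNR[0]) > params.snr_min:
            final.append(frozenset(mem))
    return set(final)


class TestExtraction:
    def test_recovers_planted_patterns(self, training6, training6_extract):
        est = training6_extract["extractor"]
        assert est.n_patterns_ == 6
        truth = training6["truth"].gene_template
        asg = est.assignments_.set_index("gene_id")
        # every pattern is dominated by a single template
        for p in est.patterns_:
            genes = asg.index[asg["pattern_id"] == p.pattern_id]
            top = truth.loc[genes].value_counts(normalize=True).iloc[0]
            assert top >= 0.95

    def test_identical_templates_collapse_to_one_pattern(self):
        _, meta = ts.generate_design("training", 6)
        tpl = ts.default_templates(30)[0]
        twin = ts.PatternTemplate("twin", dict(tpl.means), n_genes=30)
        expr, _ = ts.generate_expression(meta, [tpl, twin], noise_sd=0.05, seed=5)
        res = ts.run_extract(expr, meta)
        assert len(res["patterns"]) == 1
        assert res["patterns"][0].n_members == 60

    def test_pure_noise_yields_no_patterns(self):
        _, meta = ts.generate_design("training", 6)
        expr, _ = ts.generate_expression(meta, [], n_background_genes=500, noise_sd=0.2, seed=8)
        res = ts.run_extract(expr, meta)
        assert res["patterns"] == []
        assert not res["assignments"]["assigned"].any()

    def test_representative_is_mean_of_extraction_members(self, training6, training6_extract):
        est = training6_extract["extractor"]
        X = ts.orient_forward(training6["expression"], training6["metadata"])
        keep = GroupStructure.column_mask(training6["metadata"])
        M = X.to_numpy()[:, keep]
        for p in est.patterns_:
            np.testing.assert_allclose(p.profile, M[p.member_indices].mean(axis=0), atol=1e-12)

    def test_members_correlate_above_extraction_radius(self, training6_extract):
        est = training6_extract["extractor"]
        for p in est.patterns_:
            assert (p.member_r >= est.r_star_ - 1e-9).all()

    def test_matches_brute_force_on_small_planted_fixture(self):
        _, meta = ts.generate_design("training", 6)
        templates = [
            ts.PatternTemplate("a", {("blood", "subtoxic"): -0.6, ("blood", "toxic"): -1.6,
                                     ("liver", "subtoxic"): -0.6, ("liver", "toxic"): -1.6}, n_genes=12),
            ts.PatternTemplate("b", {("blood", "subtoxic"): 1.0, ("blood", "toxic"): 1.0,
                                     ("liver", "subtoxic"): -1.0, ("liver", "toxic"): -1.0}, n_genes=12),
        ]
        expr, _ = ts.generate_expression(meta, templates, n_background_genes=6, noise_sd=0.1, seed=13)
        params = ExtractionParams(min_cluster_size=5)
        groups = GroupStructure.from_metadata(meta)
        keep = GroupStructure.column_mask(meta)
        M = ts.orient_forward(expr, meta).to_numpy()[:, keep]

        expected = naive_extract_membership(M, groups, params)
        est = EPIGExtractor(min_cluster_size=5).fit(M, groups=groups)
        got = {frozenset(p.member_indices.tolist()) for p in est.patterns_}
        assert got == expected

    def test_empty_result_when_no_gene_passes_snr_gate(self):
        _, meta = ts.generate_design("training", 6)
        expr, _ = ts.generate_expression(meta, [], n_background_genes=50, noise_sd=0.2, seed=1)
        groups = GroupStructure.from_metadata(meta)
        keep = GroupStructure.column_mask(meta)
        est = EPIGExtractor(snr_min=1e6).fit(expr.to_numpy()[:, keep], groups=groups)
        assert est.patterns_ == [] and (est.labels_ == -1).all()

    def test_sklearn_param_interface(self):
        est = EPIGExtractor(snr_min=5.0)
        assert est.get_params()["snr_min"] == 5.0
        est.set_params(r_categorize=0.7)
        assert est.r_categorize == 0.7


class TestCategorize:
    def test_gene_equal_to_profile_assigned_with_r_one(self, training6, training6_extract):
        est = training6_extract["extractor"]
        groups = training6_extract["groups"]
        pat = est.patterns_[0]
        X = pat.profile[None, :]  # a gene identical to the representative
        asg = categorize_genes(X, est.patterns_, profile_stats(X, groups), ExtractionParams())
        row = asg.iloc[0]
        assert row["assigned"] and row["pattern_id"] == pat.pattern_id
        assert row["r"] == pytest.approx(1.0, abs=1e-9)

    def test_magnitude_gate_blocks_high_correlation(self, two_group_structure):
        rng = np.random.default_rng(4)
        base = np.concatenate([rng.normal(1.0, 0.05, 4), rng.normal(-1.0, 0.05, 4)])
        small = 0.1 * base  # r = 1 to the pattern but |S| ~ 0.2
        X = np.vstack([base] * 12 + [small])
        est = EPIGExtractor(min_cluster_size=5).fit(X, groups=two_group_structure)
        assert est.n_patterns_ == 1
        asg = est.assignments_
        assert asg.iloc[-1]["r"] > 0.9
        assert not asg.iloc[-1]["assigned"]

    def test_raising_any_threshold_never_increases_assignments(self, training6):
        expr, meta = training6["expression"], training6["metadata"]
        base = ts.run_extract(expr, meta)["assignments"]["assigned"].sum()
        for kwargs in ({"r_categorize": 0.8}, {"s_magnitude": 0.8}, {"snr_min": 5.0}):
            tighter = ts.run_extract(expr, meta, ExtractionParams(**kwargs))
            assert tighter["assignments"]["assigned"].sum() <= base

    def test_ties_break_toward_lower_pattern_id(self, two_group_structure):
        rng = np.random.default_rng(6)
        prof = np.concatenate([rng.normal(1.0, 0.02, 4), rng.normal(-1.0, 0.02, 4)])
        patterns = [
            ts.Pattern(2, prof, np.arange(1), np.ones(1), 2.0, 0.1, 20.0),
            ts.Pattern(1, prof.copy(), np.arange(1), np.ones(1), 2.0, 0.1, 20.0),
        ]
        X = prof[None, :]
        st_ = profile_stats(X, two_group_structure)
        asg = categorize_genes(X, patterns, st_, ExtractionParams())
        assert asg["pattern_id"].iloc[0] == 1


class TestCoregulationFlag:
    @pytest.mark.parametrize(
        "template_id,expected",
        [
            ("down_both_equal", True),
            ("down_both_blood_more", True),
            ("up_liver_only", False),
            ("opposite_direction", False),
        ],
    )
    def test_qualitative_shapes(self, template_id, expected):
        _, meta = ts.generate_design("training", 6)
        keep = meta["dose_class"] != "vehicle"
        col_meta = meta[keep].reset_index(drop=True)
        tpl = {t.template_id: t for t in ts.coregulation_templates()}[template_id]
        profile = expand_template(tpl, meta)
        pat = ts.Pattern(1, profile, np.arange(1), np.ones(1), 0.0, 0.0, 0.0)
        flag_coregulated(pat, col_meta)
        assert pat.coregulated is expected
        assert set(pat.s_by_tissue) == {"blood", "liver"}

    def test_single_tissue_columns_rejected(self):
        _, meta = ts.generate_design("training", 6)
        keep = (meta["dose_class"] != "vehicle") & (meta["tissue"] == "liver")
        col_meta = meta[keep].reset_index(drop=True)
        pat = ts.Pattern(1, np.zeros(keep.sum()), np.arange(1), np.ones(1), 0, 0, 0)
        with pytest.raises(ValueError, match="tissues"):
            flag_coregulated(pat, col_meta)
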