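import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import twodea.enrich as en
from twodea.influence import InfluenceTable, build_influence
from twodea.mim import BioType, MIMGraph
from twodea.synthetic import NetworkSpec, make_network, make_null_dces

from conftest import TR, edge, el
from oracles import bh_oracle, regression_es_oracle


# ----------------------------------------------------------------------
# data reading / filtering


def write_data(tmp_path, rows, header="symbol\tFC_s1\tpadj_s1"):
    path = tmp_path / "data.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def test_read_table_and_sample_discovery(tmp_path):
    path = write_data(
        tmp_path,
        ["g1\t1.5\t0.01", "g2\t-0.5\t0.2"],
        header="symbol\tFC_s1\tpadj_s1\tFC_s2\tpadj_s2",
    )
    # pad rows to the wider header
    path.write_text(
        "symbol\tFC_s1\tpadj_s1\tFC_s2\tpadj_s2\n"
        "g1\t1.5\t0.01\t0.1\t0.9\n"
        "g2\t-0.5\t0.2\t2.0\t0.001\n"
    )
    table = en.read_dce_table(path)
    assert en.data_samples(table) == ["s1", "s2"]


def test_read_table_reports_bad_value_line(tmp_path):
    path = write_data(tmp_path, ["g1\t1.5\t0.01", "g2\toops\t0.2"])
    with pytest.raises(en.DataError, match="line 3"):
        en.read_dce_table(path)


def test_read_table_rejects_unpaired_columns(tmp_path):
    path = write_data(
        tmp_path, ["g1\t1.5\t0.01"], header="symbol\tFC_s1\tpadj_s2"
    )
    with pytest.raises(en.DataError, match="unpaired"):
        en.read_dce_table(path)


@pytest.fixture
def small_graph():
    return MIMGraph(
        [
            el("g1", BioType.GENE, name="Alpha"),
            el("g2", BioType.GENE, name="Beta"),
            el("g3", BioType.GENE, name="Gamma"),
            el("m1", BioType.METABOLITE),
        ],
        [],
    )


def test_filter_thresholds_and_matching(tmp_path, small_graph):
    path = write_data(
        tmp_path,
        [
            "g1\t2.0\t0.01",   # kept
            "BETA\t0.5\t0.04", # kept via case-insensitive name, |FC| ok at 0
            "g3\t3.0\t0.20",   # p too large
            "nope\t1.0\t0.01", # unmatched
        ],
    )
    table = en.read_dce_table(path)
    dce, unmatched = en.filter_dces(table, "s1", small_graph)
    assert dce.ids == ["g1", "g2"]
    assert unmatched == ["nope"]
    assert list(dce.fc) == [2.0, 0.5]

    dce2, _ = en.filter_dces(table, "s1", small_graph, abs_fc_threshold=1.0)
    assert dce2.ids == ["g1"]


def test_filter_bio_type_restriction(tmp_path, small_graph):
    path = write_data(tmp_path, ["g1\t1.0\t0.01", "m1\t1.0\t0.01"])
    table = en.read_dce_table(path)
    dce, unmatched = en.filter_dces(
        table, "s1", small_graph, bio_types=[BioType.GENE]
    )
    assert dce.ids == ["g1"]
    assert unmatched == ["m1"]


# ----------------------------------------------------------------------
# elementary statistics


def test_level_is_linear_dot_product():
    assert en.phenotype_level([1.0], [2.0]) == 2.0
    assert en.phenotype_level([1.0, -0.5], [2.0, 2.0]) == 1.0
    rng = np.random.default_rng(0)
    i, fc = rng.uniform(-1, 1, 40), rng.normal(0, 2, 40)
    assert en.phenotype_level(i, fc) == pytest.approx(float(np.dot(i, fc)), abs=1e-12)
    assert en.phenotype_level(i, 3 * fc) == pytest.approx(
        3 * en.phenotype_level(i, fc), abs=1e-10
    )


def test_normalize_levels_across_samples():
    out = en.normalize_levels({"P": {"a": 2.0, "b": -4.0}})
    assert out == {"P": {"a": 0.5, "b": -1.0}}
    single = en.normalize_levels({"P": {"a": -3.0}})
    assert single == {"P": {"a": -1.0}}
    assert en.normalize_levels({"P": {"a": 0.0, "b": 0.0}}) == {
        "P": {"a": 0.0, "b": 0.0}
    }


def test_saturation_bounds_and_missing():
    column = {"a": 0.5, "b": -0.5, "c": 1.0}
    assert en.saturation(["a", "b", "c"], column) == 1.0
    assert en.saturation([], column) == 0.0
    assert en.saturation(["c"], column) == 0.5  # half the |I| mass
    assert en.saturation(["a"], {}) is None  # no regulators: never 0/0


def test_es_single_point_and_cancellation():
    assert en.enrichment_score([1.0], [1.0], k=2.0) == pytest.approx(1 / 3)
    assert en.enrichment_score([1.0, -1.0], [1.0, 1.0], k=2.0) == 0.0
    assert en.enrichment_score([], [], k=2.0) == 0.0
    with pytest.raises(ValueError):
        en.enrichment_score([1.0], [1.0], k=-1.0)


@pytest.mark.parametrize("seed", range(20))
def test_es_equals_regression_through_origin(seed):
    """The ES formula equals the slope of the diagonal-projection
    regression with baseline points summing k to the x^2 mass."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 60))
    i = rng.uniform(-1, 1, n)
    fc = rng.normal(0, 2, n)
    for k in (2.0, 0.5, 7.3):
        assert en.enrichment_score(i, fc, k) == pytest.approx(
            regression_es_oracle(i, fc, k), abs=1e-10
        )


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(-1, 1),
            st.floats(-8, 8, allow_nan=False),
        ),
        min_size=0,
        max_size=50,
    ),
    st.floats(0, 10),
)
def test_es_bounded_for_all_inputs(points, k):
    i = np.array([p[0] for p in points])
    fc = np.array([p[1] for p in points])
    assert abs(en.enrichment_score(i, fc, k)) <= 1.0
    assert abs(en.upstream_es(i, fc)) <= 1.0


def test_sensitivity_semantics():
    # perfect positive target: I matches FC direction at full strength
    assert en.sensitivity([1.0, -1.0], [2.0, -3.0]) == 1.0
    # perfect negative target
    assert en.sensitivity([-1.0, 1.0], [2.0, -3.0]) == -1.0
    assert en.sensitivity([], []) is None
    rng = np.random.default_rng(1)
    i, fc = rng.uniform(-1, 1, 30), rng.normal(0, 2, 30)
    assert en.sensitivity(i, fc) == pytest.approx(
        float(np.dot(i, fc) / np.abs(fc).sum()), abs=1e-12
    )


def test_specificity_semantics():
    assert en.specificity([0.0, 0.0]) == 1.0  # no influence on non-DCEs
    assert en.specificity([1.0, -1.0]) == 0.0  # full influence on all
    assert en.specificity([0.5, 0.0]) == 0.75
    assert en.specificity([]) is None


def test_upstream_es_k_term():
    # all DCEs regulated and aligned: no k mass, ES = 1
    assert en.upstream_es([1.0, 1.0], [1.0, 2.0]) == 1.0
    # none regulated: numerator 0
    assert en.upstream_es([0.0, 0.0], [1.0, 2.0]) == 0.0
    # half regulated: k = |FC| of the unregulated DCE
    i = np.array([1.0, 0.0])
    fc = np.array([2.0, -3.0])
    # numerator |I*FC|*I*FC = 4; denominator |−3| + (I*FC)^2 = 3 + 4
    assert en.upstream_es(i, fc) == pytest.approx(4.0 / 7.0, abs=1e-12)
    # strict mode sums the signed FC, here shrinking the denominator
    assert en.upstream_es(i, fc, strict_k=True) == pytest.approx(
        4.0 / (-3.0 + 4.0), abs=1e-12
    )
    # strict mode can zero the denominator; reported as 0
    assert en.upstream_es([0.0], [-0.0], strict_k=True) == 0.0


# ----------------------------------------------------------------------
# normal tail / half fit / BH


def test_two_sided_p_matches_erfc_oracle():
    for z in [0.0, 0.3, 1.0, 1.959964, 2.5, 3.7, 4.5, 6.0, 8.0, 13.9]:
        expected = float(2 * norm.sf(abs(z)))
        assert en.two_sided_p(z) == pytest.approx(expected, rel=1e-9)
    assert en.two_sided_p(0.0) == 1.0
    assert en.two_sided_p(1.959964) == pytest.approx(0.05, rel=1e-6)
    assert en.two_sided_p(-2.0) == en.two_sided_p(2.0)


def test_p_floors_at_z_cutoff():
    floor = en.two_sided_p(14.0)
    assert floor == pytest.approx(1.56e-44, rel=0.01)
    for z in (14.0, 20.0, 1e6):
        assert en.two_sided_p(z) == floor


def test_half_fit_recovers_standard_normal():
    rng = np.random.default_rng(5)
    samples = rng.normal(0, 1, 20000)
    fit = en.gaussian_half_fit(samples)
    assert fit.sigma_pos == pytest.approx(1.0, abs=0.03)
    assert fit.sigma_neg == pytest.approx(1.0, abs=0.03)
    assert not fit.pos_fallback and not fit.neg_fallback
    # scale equivariance
    fit3 = en.gaussian_half_fit(3 * samples)
    assert fit3.sigma_pos == pytest.approx(3 * fit.sigma_pos, rel=1e-9)


def test_half_fit_direction_fallback_and_degeneracy():
    fit = en.gaussian_half_fit(np.array([0.5, 1.0, 2.0]))
    assert fit.neg_fallback and fit.sigma_neg == fit.sigma_pos
    with pytest.raises(en.DegenerateNullError):
        en.gaussian_half_fit(np.array([]))
    with pytest.raises(en.DegenerateNullError):
        en.gaussian_half_fit(np.zeros(10))


def test_z_and_p_direction_matched():
    fit = en.HalfNormalFit(sigma_pos=2.0, sigma_neg=0.5)
    z, p = en.z_and_p(1.0, fit)
    assert z == 0.5
    z2, _ = en.z_and_p(-1.0, fit)
    assert z2 == -2.0
    with pytest.raises(en.DegenerateNullError):
        en.z_and_p(1.0, en.HalfNormalFit(sigma_pos=None, sigma_neg=1.0))


def test_bh_matches_hand_recipe():
    assert list(en.bh_adjust([0.01, 0.02, 0.03])) == pytest.approx(
        [0.03, 0.03, 0.03]
    )
    assert list(en.bh_adjust([0.2])) == [0.2]
    rng = np.random.default_rng(9)
    p = rng.uniform(0, 1, 57)
    assert list(en.bh_adjust(p)) == pytest.approx(list(bh_oracle(p)), abs=1e-12)
    # order equivariance: permuting inputs permutes outputs identically
    perm = rng.permutation(57)
    assert list(en.bh_adjust(p[perm])) == pytest.approx(
        list(en.bh_adjust(p)[perm]), abs=1e-12
    )
    # NaNs pass through
    out = en.bh_adjust([0.01, np.nan])
    assert np.isnan(out[1]) and out[0] == 0.01


# ----------------------------------------------------------------------
# permutation null


@pytest.fixture(scope="module")
def null_graph():
    return make_network(NetworkSpec(seed=42))


def _dce_from(graph, seed, n=12):
    data = make_null_dces(graph, n, seed=seed)
    dce, _ = en.filter_dces(data, "s1", graph)
    return dce


def test_permutation_null_is_reproducible(null_graph):
    dce = _dce_from(null_graph, 0)
    marked = set(null_graph.elements_of_type(BioType.GENE)[::2])
    # identity-sensitive statistic (a pure FC sum would be permutation-invariant)
    stat = lambda ids, fc: float(
        sum(f for e, f in zip(ids, fc) if e in marked)
    )
    a = en.permutation_null(null_graph, dce, stat, n=50, seed=7)
    b = en.permutation_null(null_graph, dce, stat, n=50, seed=7)
    assert np.array_equal(a.samples, b.samples)
    c = en.permutation_null(null_graph, dce, stat, n=50, seed=8)
    assert not np.array_equal(a.samples, c.samples)


def test_permutation_preserves_fc_multiset_and_types(null_graph):
    dce = _dce_from(null_graph, 1)
    seen = []

    def spy(ids, fc):
        seen.append(list(ids))
        return 0.0

    en.permutation_null(null_graph, dce, spy, n=20, seed=3)
    original_types = sorted(
        null_graph.element(e).bio_type.value for e in dce.ids
    )
    for ids in seen:
        assert len(ids) == len(dce.ids)
        assert len(set(ids)) == len(ids)  # distinct identities
        assert sorted(
            null_graph.element(e).bio_type.value for e in ids
        ) == original_types


def test_null_es_mean_near_zero(null_graph):
    dce = _dce_from(null_graph, 2, n=20)
    table = build_influence(null_graph, "phenotype")
    column = table.column(table.targets()[0])

    def es_stat(ids, fc):
        i = np.array([column.get(e, 0.0) for e in ids])
        return en.enrichment_score(i, fc, 2.0)

    null = en.permutation_null(null_graph, dce, es_stat, n=1000, seed=11)
    sd = null.samples.std()
    assert abs(null.samples.mean()) < 3 * sd / math.sqrt(len(null.samples)) + 1e-12


def test_permutation_with_exactly_fitting_pool(null_graph):
    # DCE list covering every metabolite: each permutation is forced to be
    # a permutation of the full type pool
    ids = null_graph.elements_of_type(BioType.METABOLITE)
    dce = en.DCESet("s1", ids, np.ones(len(ids)), np.full(len(ids), 0.01))
    seen = []
    en.permutation_null(
        null_graph, dce, lambda i, f: seen.append(sorted(i)) or 0.0, n=5, seed=0
    )
    for perm_ids in seen:
        assert perm_ids == sorted(ids)


def test_duplicate_dce_ids_rejected():
    with pytest.raises(en.DataError, match="duplicate"):
        en.DCESet("s1", ["a", "a"], np.ones(2), np.full(2, 0.01))


# ----------------------------------------------------------------------
# batch drivers


@pytest.fixture(scope="module")
def planted_downstream():
    """Map where every positive regulator of one phenotype is strongly
    upregulated: that phenotype must light up."""
    graph = make_network(NetworkSpec(seed=21))
    table = build_influence(graph, "phenotype")
    target = max(table.targets(), key=lambda v: len(table.column(v)))
    column = table.column(target)
    rows = []
    for u, score in column.items():
        if graph.element(u).bio_type is BioType.GENE:
            rows.append((u, 2.0 * np.sign(score), 0.001))
    data = pd.DataFrame(
        {
            "symbol": [r[0] for r in rows],
            "FC_s1": [r[1] for r in rows],
            "padj_s1": [r[2] for r in rows],
        }
    )
    dce, _ = en.filter_dces(data, "s1", graph)
    return graph, table, target, dce


def test_downstream_planted_phenotype_is_top_hit(planted_downstream):
    graph, table, target, dce = planted_downstream
    res = en.run_downstream(graph, table, [dce], n=500, seed=1)
    row = res[res.element == target].iloc[0]
    assert row.es > 0
    assert row.level > 0
    assert row.z > 0
    assert row.p == res.p.min()


def test_downstream_statistic_mode_ordering(planted_downstream):
    graph, table, _, dce = planted_downstream
    kwargs = dict(n=200, seed=5)
    res_max = en.run_downstream(graph, table, [dce], statistic_mode="max_p", **kwargs)
    res_min = en.run_downstream(graph, table, [dce], statistic_mode="min_p", **kwargs)
    res_es = en.run_downstream(graph, table, [dce], statistic_mode="es", **kwargs)
    res_level = en.run_downstream(graph, table, [dce], statistic_mode="level", **kwargs)
    for i in range(len(res_max)):
        pmax, pmin = res_max.p.iloc[i], res_min.p.iloc[i]
        pes, plev = res_es.p.iloc[i], res_level.p.iloc[i]
        if not (np.isnan(pmax) or np.isnan(pmin)):
            assert pmax >= pmin
            assert pmax == max(pes, plev) and pmin == min(pes, plev)


def test_downstream_is_deterministic(planted_downstream):
    graph, table, _, dce = planted_downstream
    a = en.run_downstream(graph, table, [dce], n=100, seed=9)
    b = en.run_downstream(graph, table, [dce], n=100, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_downstream_adaptive_k_uses_max_fc(planted_downstream):
    graph, table, _, dce = planted_downstream
    res = en.run_downstream(graph, table, [dce], n=10, seed=0, k_mode="adaptive")
    assert (res.k == np.abs(dce.fc).max()).all()


def test_downstream_level_norm_across_samples(planted_downstream):
    graph, table, _, dce = planted_downstream
    half = en.DCESet(
        "s2", dce.ids, dce.fc * 0.5, dce.adj_p, dce.filter_spec
    )
    res = en.run_downstream(graph, table, [dce, half], n=10, seed=0)
    for v in res.element.unique():
        sub = res[res.element == v]
        peak = sub.level.abs().max()
        if peak > 0:
            assert sub.level_norm.abs().max() == pytest.approx(1.0)
        else:
            assert (sub.level_norm == 0).all()


def test_downstream_empty_dces_yield_missing_stats(null_graph):
    table = build_influence(null_graph, "phenotype")
    empty = en.DCESet("s1", [], np.empty(0), np.empty(0))
    res = en.run_downstream(null_graph, table, [empty], n=10, seed=0)
    assert len(res) == len(table.targets())
    assert (res.level == 0).all()
    assert res.p.isna().all() and res.adj_p.isna().all()


@pytest.fixture(scope="module")
def upstream_case():
    """TF 'X' directly induces every DCE; decoy 'D' regulates only
    non-DCE genes."""
    genes = [el(f"g{i}", BioType.GENE) for i in range(8)]
    graph = MIMGraph(
        [el("X"), el("D")] + genes,
        [edge("X", 1, f"g{i}", TR) for i in range(4)]
        + [edge("D", 1, f"g{i}", TR) for i in range(4, 6)],
    )
    table = build_influence(graph, "transcriptional")
    dce = en.DCESet(
        "s1", [f"g{i}" for i in range(4)], np.array([1.0, 2.0, 0.5, 1.5]),
        np.full(4, 0.01),
    )
    return graph, table, dce


def test_upstream_perfect_inducer_ranks_first(upstream_case):
    graph, table, dce = upstream_case
    res = en.run_upstream(graph, table, [dce], n=100, seed=2)
    top = res.iloc[0]
    assert top.element == "X"
    assert top.sensitivity == 1.0
    assert top["rank"] == 1
    decoy = res[res.element == "D"].iloc[0]
    assert decoy.sensitivity == 0.0
    # D touches 2 of the 4 non-DCE genes at |I| = 1
    assert decoy.specificity == pytest.approx(0.5)
    # X influences no non-DCE gene: perfectly specific
    assert top.specificity == 1.0


def test_upstream_type_filter_applied_after_fdr(upstream_case):
    graph, table, dce = upstream_case
    full = en.run_upstream(graph, table, [dce], n=50, seed=2)
    filtered = en.run_upstream(
        graph, table, [dce], n=50, seed=2, target_types=[BioType.PROTEIN]
    )
    assert set(filtered.element) <= set(full.element)
    # adjusted p computed on the unfiltered candidate pool
    for e in filtered.element:
        assert (
            filtered[filtered.element == e].adj_p.iloc[0]
            == full[full.element == e].adj_p.iloc[0]
        )


def test_upstream_deterministic(upstream_case):
    graph, table, dce = upstream_case
    a = en.run_upstream(graph, table, [dce], n=50, seed=4)
    b = en.run_upstream(graph, table, [dce], n=50, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_in_silico_perturbation_linearity(null_graph):
    table = build_influence(null_graph, "phenotype")
    target = table.targets()[0]
    column = table.column(target)
    regulators = sorted(column)[:2]
    single = {
        r: en.in_silico_perturbation(null_graph, table, [(r, 1.0)])
        for r in regulators
    }
    for r in regulators:
        level = single[r][single[r].element == target].level.iloc[0]
        assert level == pytest.approx(column[r])
        flipped = en.in_silico_perturbation(null_graph, table, [(r, -1.0)])
        assert flipped[flipped.element == target].level.iloc[0] == pytest.approx(
            -level
        )
    both = en.in_silico_perturbation(
        null_graph, table, [(regulators[0], 1.0), (regulators[1], 1.0)]
    )
    assert both[both.element == target].level.iloc[0] == pytest.approx(
        sum(
            single[r][single[r].element == target].level.iloc[0]
            for r in regulators
        )
    )
    with pytest.raises(en.DataError, match="nowhere"):
        en.in_silico_perturbation(null_graph, table, [("nowhere", 1.0)])
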