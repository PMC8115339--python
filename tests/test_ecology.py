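"""Dereplication, recruitment normalization, environmental pairing and
canonical correspondence analysis."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from magstream import (
    AniPair,
    GenomeQuality,
    InputError,
    cca,
    dereplicate_by_ani,
    pair_environment,
    relative_fraction,
    rpkm,
)

Q = {
    "A": GenomeQuality(90.0, 1.0, 1_000_000),
    "B": GenomeQuality(80.0, 1.0, 1_100_000),
    "C": GenomeQuality(90.0, 2.0, 900_000),
}


def test_ani_pair_above_threshold_clusters():
    clusters, reps = dereplicate_by_ani([AniPair("A", "B", 99.0)], Q)
    assert clusters == [frozenset({"A", "B"}), frozenset({"C"})]
    assert reps[frozenset({"A", "B"})] == "A"  # higher completeness wins


def test_ani_below_threshold_stays_split():
    clusters, _ = dereplicate_by_ani([AniPair("A", "B", 98.4)], Q)
    assert all(len(c) == 1 for c in clusters)


def test_ani_single_linkage_chain():
    pairs = [AniPair("A", "B", 99.0), AniPair("B", "C", 99.0),
             AniPair("A", "C", 97.0)]
    clusters, _ = dereplicate_by_ani(pairs, Q)
    assert clusters == [frozenset({"A", "B", "C"})]


def test_ani_directional_values_averaged():
    # mean of 98.0 and 99.2 = 98.6 >= 98.5 -> clustered
    clusters, _ = dereplicate_by_ani([AniPair("A", "B", 98.0, 99.2)], Q)
    assert frozenset({"A", "B"}) in clusters


def test_representative_tie_breaks():
    # equal completeness: lower contamination wins over larger assembly
    clusters, reps = dereplicate_by_ani([AniPair("A", "C", 99.0)], Q)
    assert reps[frozenset({"A", "C"})] == "A"


def test_ani_missing_quality_is_error():
    with pytest.raises(InputError, match="missing from quality"):
        dereplicate_by_ani([AniPair("A", "Z", 99.0)], Q)


def test_relative_fraction_examples():
    assert relative_fraction(10, 1000) == 0.01
    assert relative_fraction(0, 1000) == 0.0
    assert relative_fraction(1000, 1000) == 1.0
    with pytest.raises(InputError, match="exceed"):
        relative_fraction(1001, 1000)


def test_rpkm_examples_and_linearity():
    assert rpkm(10, 2000, 10**6) == 5.0
    assert rpkm(1, 1000, 10**6) == 1.0
    assert rpkm(20, 2000, 10**6) == 10.0
    with pytest.raises(InputError):
        rpkm(1, 0, 10**6)


def test_rpkm_invariant_under_joint_scaling():
    assert rpkm(30, 5000, 2 * 10**6) == pytest.approx(
        rpkm(3 * 30, 5000, 3 * 2 * 10**6)
    )


def _env_frame(rows):
    return pd.DataFrame(rows, columns=["station", "depth", "nitrate", "temp"])


def test_pair_environment_mean_within_tolerance():
    meta = pd.DataFrame({"station": ["S1"], "depth": [20.5]},
                        index=pd.Index(["m1"], name="sample_id"))
    env = _env_frame([("S1", 20.0, 5.0, np.nan), ("S1", 21.0, 7.0, np.nan)])
    out = pair_environment(meta, env)
    assert out.loc["m1", "nitrate"] == 6.0
    assert np.isnan(out.loc["m1", "temp"])  # never measured


def test_pair_environment_outside_tolerance_is_missing():
    meta = pd.DataFrame({"station": ["S1"], "depth": [20.5]},
                        index=pd.Index(["m1"], name="sample_id"))
    env = _env_frame([("S1", 22.0, 5.0, 10.0)])
    with pytest.warns(UserWarning, match="no environmental cast"):
        out = pair_environment(meta, env)
    assert out.loc["m1"].isna().all()


def test_pair_environment_duplicate_casts_averaged():
    meta = pd.DataFrame({"station": ["S1"], "depth": [20.5]},
                        index=pd.Index(["m1"], name="sample_id"))
    env = _env_frame([("S1", 20.5, np.nan, 10.0), ("S1", 20.5, np.nan, 12.0)])
    assert pair_environment(meta, env).loc["m1", "temp"] == 11.0


def test_pair_environment_requires_same_station():
    meta = pd.DataFrame({"station": ["S1"], "depth": [20.0]},
                        index=pd.Index(["m1"], name="sample_id"))
    env = _env_frame([("S2", 20.0, 5.0, 10.0)])
    with pytest.warns(UserWarning):
        out = pair_environment(meta, env)
    assert out.loc["m1"].isna().all()


def _random_cca_instance(seed, n=10, m=8, q=3):
    rng = np.random.default_rng(seed)
    y = pd.DataFrame(rng.poisson(15, size=(n, m)) + 1.0,
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"g{j}" for j in range(m)])
    x = pd.DataFrame(rng.normal(size=(n, q)), index=y.index,
                     columns=[f"v{k}" for k in range(q)])
    return y, x


def test_cca_eigenvalues_bounded_and_sorted():
    y, x = _random_cca_instance(0)
    res = cca(y, x)
    eig = res.eigenvalues
    assert np.all(eig >= 0) and np.all(eig <= 1)
    assert np.all(np.diff(eig) <= 1e-12)
    assert eig.sum() <= res.total_inertia + 1e-12


def test_cca_indicator_basis_recovers_total_inertia():
    """With a full sample-indicator design the constraint is vacuous and
    constrained inertia equals total inertia (plain CA limit)."""
    y, _ = _random_cca_instance(1, n=6, m=5)
    x = pd.DataFrame(np.eye(6)[:, :5], index=y.index,
                     columns=[f"d{i}" for i in range(5)])
    res = cca(y, x, transform=False)
    assert res.eigenvalues.sum() == pytest.approx(res.total_inertia)


def test_cca_prunes_constant_variable():
    y, x = _random_cca_instance(2)
    x["flat"] = 1.0
    with pytest.warns(UserWarning, match="pruned"):
        res = cca(y, x)
    assert "flat" not in res.env_variables
    assert len(res.eigenvalues) == 3


def test_cca_coverage_filter_drops_sparse_variable():
    y, x = _random_cca_instance(3)
    x.loc[x.index[:5], "v2"] = np.nan  # 50% coverage < 90%
    res = cca(y, x)
    assert res.env_variables == ["v0", "v1"]


def test_cca_strong_gradient_dominates_first_axis():
    rng = np.random.default_rng(4)
    grad = np.linspace(0, 1, 12)
    # genomes respond unimodally along the gradient; niches broad enough
    # that the arch effect does not split the gradient across axes
    optima = np.linspace(0, 1, 6)
    y = pd.DataFrame(
        200 * np.exp(-((grad[:, None] - optima[None, :]) ** 2) / 0.2)
        + rng.poisson(1, size=(12, 6)),
        index=[f"s{i}" for i in range(12)],
        columns=[f"g{j}" for j in range(6)],
    )
    x = pd.DataFrame({"grad": grad, "noise": rng.normal(size=12)},
                     index=y.index)
    res = cca(y, x, transform=False)
    assert res.eigenvalues[0] / res.eigenvalues.sum() > 0.9
    assert abs(res.biplot_scores.loc["grad", "CCA1"]) > abs(
        res.biplot_scores.loc["noise", "CCA1"]
    )


def test_cca_first_eigenvalue_within_permutation_null():
    """Random env variables: the observed first eigenvalue should sit
    inside the central 95% of its permutation null."""
    y, x = _random_cca_instance(5)
    obs = cca(y, x).eigenvalues[0]
    rng = np.random.default_rng(6)
    null = []
    for _ in range(100):
        perm = x.sample(frac=1.0, random_state=rng.integers(2**31)).set_axis(
            x.index
        )
        null.append(cca(y, perm).eigenvalues[0])
    lo, hi = np.quantile(null, [0.025, 0.975])
    assert lo <= obs <= hi


def test_cca_matches_vegan_eigenvalues(tmp_path):
    """Independent oracle: R vegan::cca on the same matrices."""
    y, x = _random_cca_instance(8)
    y.to_csv(tmp_path / "y.csv", index=False)
    x.to_csv(tmp_path / "x.csv", index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.csv("{tmp_path}/y.csv"))
        X <- as.data.frame(read.csv("{tmp_path}/x.csv"))
        m <- cca(Y ~ ., data = X)
        cat(sprintf("%.12f\\n", m$CCA$eig))
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    vegan_eig = np.array([float(v) for v in out.stdout.split()])
    res = cca(y, x, transform=False)
    np.testing.assert_allclose(res.eigenvalues, vegan_eig, atol=1e-8)
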