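"""PCA, trend clustering, correlation screens, concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pcproteo.compartment import (
    pca,
    peptide_protein_concordance,
    size_correlation,
    marker_correlation,
    trend_clusters,
)
from pcproteo.io import QuantMatrix


def _qm(vals, features=None, samples=None, level="protein"):
    vals = np.asarray(vals, dtype=float)
    features = features or [f"F{i}" for i in range(vals.shape[0])]
    samples = samples or [f"S{j}" for j in range(vals.shape[1])]
    return QuantMatrix(
        data=pd.DataFrame(vals, index=features, columns=samples), level=level
    )


# ---------------------------------------------------------------------------
# PCA


def test_pca_duplicated_samples_get_identical_scores(rng):
    X = rng.normal(0, 1, size=(10, 4))
    X = np.hstack([X, X[:, [0]]])  # sample 4 duplicates sample 0
    res = pca(_qm(X))
    assert np.allclose(res.scores.iloc[0], res.scores.iloc[4], atol=1e-9)


def test_pca_rank_one_matrix():
    u = np.array([1.0, 2.0, 3.0])
    v = np.array([1.0, -1.0, 0.5, 2.0])
    res = pca(_qm(np.outer(u, v)))
    assert res.variance_explained[0] == pytest.approx(100.0)


def test_pca_matches_eigendecomposition_oracle():
    X = np.array([[2.0, 0.0, 1.0], [0.0, 1.0, 3.0], [1.0, 1.0, 1.0]])
    res = pca(_qm(X))
    # oracle: eigen-decomposition of the covariance of centered samples
    Y = X.T - X.T.mean(axis=0)
    w, V = np.linalg.eigh(Y.T @ Y)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    assert np.allclose(res.variance_explained / 100 * w.sum(), w, atol=1e-9)
    for k in range(2):  # compare score magnitudes up to sign
        assert np.allclose(
            np.abs(res.scores.iloc[:, k].to_numpy()), np.abs(Y @ V[:, k]), atol=1e-9
        )


def test_pca_reconstruction_and_monotone_variance(rng):
    X = rng.normal(0, 1, size=(8, 6))
    res = pca(_qm(X))
    ve = res.variance_explained
    assert np.all(np.diff(ve) <= 1e-12) and np.all(ve >= 0)
    assert ve.sum() <= 100 + 1e-9
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    Y = X.T - X.T.mean(axis=0)
    assert np.allclose(recon, Y, atol=1e-9)


def test_pca_rejects_missing(rng):
    X = rng.normal(0, 1, size=(5, 4))
    X[0, 0] = np.nan
    with pytest.raises(ValueError):
        pca(_qm(X))


# ---------------------------------------------------------------------------
# trends


def _trend_meta():
    ids = [f"S{i}" for i in range(12)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "compartment": ["NAT"] * 4 + ["PC"] * 4 + ["TUMOR"] * 4,
        }
    ).set_index("sample_id", drop=False)


def test_trend_assignment_basic():
    meta = _trend_meta()
    inc = np.r_[np.full(4, -1.0), np.full(4, 0.0), np.full(4, 1.0)]
    flat = np.r_[np.full(12, 0.0)]
    noise = np.array([0.1, -0.1] * 6)
    X = np.vstack([inc, -inc, flat + noise])
    res = trend_clusters(_qm(X), meta)
    assert list(res["cluster"]) == ["increasing", "decreasing", "none"]


def test_trend_relabel_swap_symmetry(rng):
    meta = _trend_meta()
    X = rng.normal(0, 1, size=(40, 12))
    X[:10] += np.r_[np.full(4, -1.0), np.full(4, 0.0), np.full(4, 1.0)]
    res = trend_clusters(_qm(X), meta)
    swapped = meta.copy()
    swapped["compartment"] = swapped["compartment"].map(
        {"NAT": "TUMOR", "TUMOR": "NAT", "PC": "PC"}
    )
    res2 = trend_clusters(_qm(X), swapped)
    flip = {"increasing": "decreasing", "decreasing": "increasing", "none": "none"}
    assert list(res2["cluster"]) == [flip[c] for c in res["cluster"]]


def test_trend_missing_compartment_errors(rng):
    meta = _trend_meta()
    bad = meta[meta["compartment"] != "PC"]
    X = rng.normal(0, 1, size=(5, len(bad)))
    with pytest.raises(ValueError):
        trend_clusters(_qm(X, samples=list(bad.index)), bad)


# ---------------------------------------------------------------------------
# size correlation


def test_size_correlation_exact_linear():
    d = pd.Series(
        np.linspace(10, 60, 8), index=[f"S{i}" for i in range(8)]
    )
    X = np.vstack([2 + 0.05 * d.to_numpy(), 5 - 0.02 * d.to_numpy()])
    res = size_correlation(_qm(X), d)
    assert res.iloc[0]["r"] == pytest.approx(1.0)
    assert res.iloc[0]["p"] < 1e-10
    assert res.iloc[1]["r"] == pytest.approx(-1.0)
    assert list(res["direction"]) == ["positive", "negative"]


def test_size_correlation_affine_invariance(rng):
    d = pd.Series(rng.uniform(10, 80, 10), index=[f"S{i}" for i in range(10)])
    X = rng.normal(0, 1, size=(20, 10))
    r1 = size_correlation(_qm(X), d)["r"]
    r2 = size_correlation(_qm(X), d * 3.2 + 7.0)["r"]
    assert np.allclose(r1, r2, atol=1e-12)


def test_size_correlation_constant_feature_flagged(rng):
    d = pd.Series(rng.uniform(10, 80, 8), index=[f"S{i}" for i in range(8)])
    X = np.vstack([np.full(8, 3.0), rng.normal(0, 1, 8)])
    res = size_correlation(_qm(X), d)
    assert res.iloc[0]["constant"]
    assert res.iloc[0]["direction"] == "ns"


def test_size_correlation_sets_disjoint(rng):
    d = pd.Series(rng.uniform(10, 80, 20), index=[f"S{i}" for i in range(20)])
    X = rng.normal(0, 1, size=(100, 20))
    res = size_correlation(_qm(X), d)
    pos = set(res.index[res["direction"] == "positive"])
    neg = set(res.index[res["direction"] == "negative"])
    assert pos.isdisjoint(neg)


def test_size_correlation_needs_samples(rng):
    d = pd.Series([10.0, 20.0], index=["S0", "S1"])
    with pytest.raises(ValueError):
        size_correlation(_qm(rng.normal(size=(3, 2))), d)


def test_size_correlation_matches_scipy(rng):
    from scipy import stats

    d = pd.Series(rng.uniform(10, 80, 15), index=[f"S{i}" for i in range(15)])
    X = rng.normal(0, 1, size=(10, 15))
    res = size_correlation(_qm(X), d)
    for i in range(10):
        r_ref, p_ref = stats.pearsonr(X[i], d.to_numpy())
        assert res.iloc[i]["r"] == pytest.approx(r_ref, abs=1e-12)
        assert res.iloc[i]["p"] == pytest.approx(p_ref, rel=1e-9)


# ---------------------------------------------------------------------------
# marker correlation


def test_marker_correlation_self_is_one(rng):
    meta = _trend_meta()
    X = rng.normal(0, 1, size=(3, 12))
    X[1] = X[0]  # panel member duplicates the anchor
    qm = _qm(X, features=["PCNA", "MCM2", "MCM3"])
    res = marker_correlation(qm, meta, "PCNA", ["MCM2", "MCM3"])
    dup = res[res["feature"] == "MCM2"]
    assert np.allclose(dup["r"], 1.0)
    assert (res["n"] == 4).all()


def test_marker_correlation_absent_feature(rng):
    meta = _trend_meta()
    qm = _qm(rng.normal(0, 1, (2, 12)), features=["PCNA", "MCM2"])
    res = marker_correlation(qm, meta, "PCNA", ["MCM2", "GONE"])
    gone = res[res["feature"] == "GONE"]
    assert gone["r"].isna().all()


# ---------------------------------------------------------------------------
# concordance


def _da(idx, fcs, adj, sig=None):
    return pd.DataFrame(
        {
            "log2fc": fcs,
            "adj_p": adj,
            "significant": sig
            if sig is not None
            else [a <= 0.05 and abs(f) >= np.log2(1.5) for f, a in zip(fcs, adj)],
        },
        index=idx,
    )


def test_concordance_exact_match():
    peps = [f"p{i}" for i in range(6)]
    prots = ["A", "A", "B", "B", "C", "C"]
    fcs = [1.0, 1.0, -0.5, -0.5, 0.2, 0.2]
    pep_da = _da(peps, fcs, [0.01] * 6)
    prot_da = _da(["A", "B", "C"], [1.0, -0.5, 0.2], [0.01] * 3)
    r, disc = peptide_protein_concordance(
        pep_da, prot_da, pd.Series(prots, index=peps)
    )
    assert r == pytest.approx(1.0)
    assert disc.empty


def test_concordance_flags_opposite_regulation():
    peps = ["p0", "p1", "p2"]
    pep_da = _da(peps, [1.0, 1.0, 0.1], [0.01, 0.01, 0.9])
    prot_da = _da(["A", "B"], [-1.0, 1.0], [0.01, 0.01])
    mapping = pd.Series(["A", "B", "B"], index=peps)
    _, disc = peptide_protein_concordance(pep_da, prot_da, mapping)
    assert list(disc.index) == ["p0"]  # significant peptide, opposite protein


def test_concordance_flags_nonsignificant_parent():
    peps = ["p0", "p1"]
    pep_da = _da(peps, [1.0, 1.0], [0.01, 0.01])
    prot_da = _da(["A", "B"], [0.9, 1.0], [0.5, 0.01], sig=[False, True])
    _, disc = peptide_protein_concordance(
        pep_da, prot_da, pd.Series(["A", "B"], index=peps)
    )
    assert list(disc.index) == ["p0"]


def test_concordance_requires_overlap():
    pep_da = _da(["p0"], [1.0], [0.01])
    prot_da = _da(["Z"], [1.0], [0.01])
    with pytest.raises(ValueError):
        peptide_protein_concordance(
            pep_da, prot_da, pd.Series(["A"], index=["p0"])
        )


# ---------------------------------------------------------------------------
# generator-truth recovery


def test_trend_planted_recovery():
    """Planted monotone trends are recovered; null features rarely called."""
    n_nat, n_pc, n_tum = 31, 45, 54
    cols = (
        [f"N{i}" for i in range(n_nat)]
        + [f"P{i}" for i in range(n_pc)]
        + [f"T{i}" for i in range(n_tum)]
    )
    meta = pd.DataFrame(
        {
            "sample_id": cols,
            "compartment": ["NAT"] * n_nat + ["PC"] * n_pc + ["TUMOR"] * n_tum,
        }
    ).set_index("sample_id", drop=False)
    grade = np.r_[
        np.full(n_nat, -0.75), np.full(n_pc, 0.0), np.full(n_tum, 0.75)
    ]  # span 1.5 sd
    for seed in range(10):
        r = np.random.default_rng(300 + seed)
        X = r.normal(0, 1, size=(1000, len(cols)))
        X[:100] += grade
        X[100:200] -= grade
        res = trend_clusters(_qm(X, samples=cols), meta)
        inc_ok = (res["cluster"].iloc[:100] == "increasing").mean()
        dec_ok = (res["cluster"].iloc[100:200] == "decreasing").mean()
        null_called = (res["cluster"].iloc[200:] != "none").mean()
        assert inc_ok >= 0.9 and dec_ok >= 0.9
        assert null_called <= 0.05


def test_marker_null_r_bound():
    """Independent Gaussians at n = 54 rarely exceed |r| = 0.27."""
    r = np.random.default_rng(17)
    inside = 0
    for _ in range(400):
        a, b = r.normal(0, 1, 54), r.normal(0, 1, 54)
        if abs(np.corrcoef(a, b)[0, 1]) < 0.27:
            inside += 1
    assert inside / 400 >= 0.93


def test_marker_coupling_recovered_in_tumor_only():
    """Anchor-panel coupling planted in tumor shows up as tumor r > NAT r."""
    from pcproteo.quant import rollup_proteins
    from pcproteo.simulate import simulate_cohort

    hits = 0
    n_seeds = 10
    for seed in range(1, n_seeds + 1):
        cohort = simulate_cohort(seed=seed)
        acc = {p.gene: p.accession for p in cohort.proteins}
        marker_accs = {acc[g] for g in ("PCNA", "MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7")}
        info = cohort.pep_info
        sel = info.index[
            ~info["is_semi"]
            & info["protein_group"].isin(marker_accs)
        ]
        pep_qm = QuantMatrix(
            data=np.log2(cohort.intensities.loc[sel]), level="peptide"
        )
        prot_qm, _ = rollup_proteins(pep_qm, info.loc[sel])
        res = marker_correlation(
            prot_qm,
            cohort.metadata,
            acc["PCNA"],
            [acc[f"MCM{i}"] for i in range(2, 8)],
        )
        tum = res[res["compartment"] == "TUMOR"]["r"].mean()
        nat = res[res["compartment"] == "NAT"]["r"].mean()
        hits += tum > nat
    assert hits >= int(np.ceil(0.95 * n_seeds))


def test_discordant_peptide_recovery():
    """Peptides with planted cleavage-driven shifts are flagged discordant."""
    from pcproteo.da import moderated_ttest
    from pcproteo.quant import (
        completeness_filter,
        impute_mnar,
        normalize_median,
        rollup_proteins,
    )
    from pcproteo.simulate import simulate_cohort

    recalls, precisions = [], []
    for seed in range(1, 11):
        cohort = simulate_cohort(seed=seed)
        info = cohort.pep_info
        full_ids = info.index[~info["is_semi"]]
        pep_qm = QuantMatrix(
            data=np.log2(cohort.intensities.loc[full_ids]), level="peptide"
        )
        prot_qm, _ = rollup_proteins(pep_qm, info.loc[full_ids])
        prot_qm = normalize_median(prot_qm)
        ext, _ = completeness_filter(prot_qm, cohort.metadata, "extended")
        ext = impute_mnar(ext, seed=seed)
        comp = cohort.metadata["compartment"]
        tum = list(comp.index[comp == "TUMOR"])
        nat = list(comp.index[comp == "NAT"])
        pep_da = moderated_ttest(pep_qm, tum, nat)
        prot_da = moderated_ttest(ext, tum, nat)
        mapping = info.loc[full_ids, "protein_group"].str.split(";").str[0]
        _, disc = peptide_protein_concordance(pep_da, prot_da, mapping)
        truth = set(cohort.truth["discordant_peptides"])
        flagged = set(disc.index)
        tp = len(flagged & truth)
        recalls.append(tp / max(1, len(truth)))
        precisions.append(tp / max(1, len(flagged)))
    assert np.mean(recalls) >= 0.7
    assert np.mean(precisions) >= 0.7
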