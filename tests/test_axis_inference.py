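"""Diffusion map, pseudotime, orientation and binned profiles."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from zonatlas import axis_inference as ai
from zonatlas import preprocessing as pp
from zonatlas import synthetic_data as syn
from zonatlas.errors import ValidationError


def _chain_embedding(n=30, dup=None, k=5):
    """Spots equispaced along PC1 (a 1-D chain); optionally duplicate one."""
    pcs = np.zeros((n, 3))
    pcs[:, 0] = np.arange(n, dtype=float)
    if dup is not None:
        pcs[dup[1]] = pcs[dup[0]]
    nn_graph = sp.csr_matrix(
        np.fromfunction(
            lambda i, j: (np.abs(i - j) <= k) & (i != j), (n, n), dtype=int
        ).astype(float)
    )
    return pp.EmbeddingResult(
        pc_scores=pcs,
        neighbor_graph=nn_graph,
        cluster_labels=np.zeros(n, dtype=int),
        major_flag=np.ones(1, dtype=bool),
        k_neighbors=k,
    )


def test_first_component_monotone_along_a_chain():
    emb = _chain_embedding()
    dc = ai.diffusion_map(emb, n_dc=3)
    d1 = np.diff(dc[:, 0])
    assert np.all(d1 > 0) or np.all(d1 < 0)


def test_duplicate_spots_get_identical_components():
    emb = _chain_embedding(dup=(10, 11))
    dc = ai.diffusion_map(emb, n_dc=3)
    np.testing.assert_allclose(dc[10], dc[11], atol=1e-10)


def test_components_match_dense_eigendecomposition_oracle():
    # 6-node path graph with a hand-built kernel; oracle = brute-force
    # eigendecomposition of the row-normalized transition matrix
    rng = np.random.default_rng(0)
    x = np.sort(rng.random(6))
    d = np.abs(x[:, None] - x[None, :])
    kernel = np.exp(-(d**2) / 0.1)
    dc = ai._components_from_kernel(kernel, n_dc=3, scaling="eigenvalue")

    p = kernel / kernel.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(p)
    order = np.argsort(evals.real)[::-1]
    evals, evecs = evals.real[order], evecs.real[:, order]
    for j in range(3):
        v = evecs[:, j + 1]
        v = v / np.linalg.norm(v)
        got = dc[:, j] / np.abs(evals[j + 1])
        # eigenvectors match up to sign
        err = min(np.abs(got - v).max(), np.abs(got + v).max())
        assert err < 1e-8


def test_disconnected_graph_raises_with_advice():
    emb = _chain_embedding(n=20, k=3)
    g = emb.neighbor_graph.toarray()
    g[:10, 10:] = 0
    g[10:, :10] = 0
    emb.neighbor_graph = sp.csr_matrix(g)
    with pytest.raises(ValidationError, match="k_neighbors"):
        ai.diffusion_map(emb)


def test_pseudotime_zero_at_root_and_monotone_on_chain():
    emb = _chain_embedding()
    dc = ai.diffusion_map(emb, n_dc=2)
    labels = np.zeros(30, dtype=int)
    labels[:3] = 1  # root cluster at the chain start
    axis = ai.pseudotime(dc, labels, root_cluster=1)
    root_idx = int(np.flatnonzero(axis.barcodes == axis.root_spot)[0])
    assert axis.t[root_idx] == pytest.approx(0.0)
    assert axis.t.min() == 0.0 and axis.t.max() == 1.0
    rho = spearmanr(axis.t, np.arange(30)).statistic
    assert abs(rho) > 0.99


def test_pseudotime_empty_root_cluster_raises():
    with pytest.raises(ValidationError, match="empty"):
        ai.pseudotime(np.zeros((5, 2)), np.zeros(5, dtype=int), root_cluster=3)


def test_pseudotime_invariant_under_pc_rotation():
    emb = _chain_embedding()
    dc = ai.diffusion_map(emb, n_dc=2)
    theta = 0.7
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    emb_rot = pp.EmbeddingResult(
        pc_scores=emb.pc_scores @ rot.T,
        neighbor_graph=emb.neighbor_graph,
        cluster_labels=emb.cluster_labels,
        major_flag=emb.major_flag,
        k_neighbors=emb.k_neighbors,
    )
    dc_rot = ai.diffusion_map(emb_rot, n_dc=2)
    labels = np.zeros(30, dtype=int)
    labels[:3] = 1
    t1 = ai.pseudotime(dc, labels, 1).t
    t2 = ai.pseudotime(dc_rot, labels, 1).t
    np.testing.assert_allclose(t1, t2, atol=1e-8)


# -- orientation ------------------------------------------------------------

def _axis(t):
    n = len(t)
    return ai.PseudotimeAxis(
        t=np.asarray(t, dtype=float),
        spots=np.arange(n),
        barcodes=np.array([f"b{i}" for i in range(n)], dtype=object),
        root_spot="b0",
        orientation_applied=False,
        diffusion_components=np.zeros((n, 1)),
    )


def _marker_matrix(t):
    # portal marker decreasing in t, central marker increasing
    return np.vstack([1.0 - np.asarray(t), np.asarray(t)])


def test_orientation_is_a_no_op_when_portal_is_already_at_zero():
    t = np.linspace(0, 1, 11)
    ax = ai.orient_axis(_axis(t), _marker_matrix(t), ["P", "C"], ["P"], ["C"])
    np.testing.assert_allclose(ax.t, t)
    assert ax.orientation_applied


def test_orientation_flips_a_reversed_axis_and_is_idempotent():
    t = np.linspace(0, 1, 11)
    ax_flipped = ai.orient_axis(
        _axis(1 - t), _marker_matrix(t), ["P", "C"], ["P"], ["C"]
    )
    np.testing.assert_allclose(ax_flipped.t, t)
    again = ai.orient_axis(ax_flipped, _marker_matrix(t), ["P", "C"], ["P"], ["C"])
    np.testing.assert_allclose(again.t, ax_flipped.t)


def test_orientation_requires_markers():
    t = np.linspace(0, 1, 11)
    with pytest.raises(ValidationError, match="marker"):
        ai.orient_axis(_axis(t), _marker_matrix(t), ["P", "C"], ["absent"], ["C"])


def test_oriented_axis_tracks_truth_direction(default_study):
    # after orientation, t must increase with the true pericentral coordinate
    t_true = default_study.spot_truth("t_true")[default_study.axis.spots]
    rho = spearmanr(default_study.axis.t, t_true).statistic
    assert rho > 0


# -- binned profiles --------------------------------------------------------

def test_binned_profile_arithmetic():
    t = np.array([0.1, 0.2, 0.8, 0.9])
    norm = np.array([[1.0, 3.0, 5.0, 7.0]])
    prof = ai.bin_profiles(norm, ["g"], _axis(t), n_bins=2)
    tab = prof.table
    np.testing.assert_allclose(tab["mean"].to_numpy(), [2.0, 6.0])
    np.testing.assert_allclose(tab["se"].to_numpy(), [1.0, 1.0])
    assert list(tab["n"]) == [2, 2]


def test_constant_gene_gives_flat_profile_and_empty_bins_are_nan():
    t = np.array([0.05, 0.1, 0.95])
    norm = np.array([[2.0, 2.0, 2.0]])
    prof = ai.bin_profiles(norm, ["g"], _axis(t), n_bins=4)
    tab = prof.table
    means = tab["mean"].to_numpy()
    assert means[0] == 2.0 and means[3] == 2.0
    assert np.isnan(means[1]) and np.isnan(means[2])
    assert tab["se"].to_numpy()[0] == 0.0


def test_midzonal_gene_peaks_in_central_bins(default_study):
    # bin noisy counts of centre-peaked genes along the known coordinate:
    # the profile argmax must fall in the central third of the bins
    mid = [
        s for s in syn.default_gene_panel(120, seed=1)
        if s.family == "gauss" and abs(s.params["mu"] - 0.5) < 0.05
    ]
    assert len(mid) >= 3
    t_true = default_study.spot_truth("t_true")
    assert default_study.ds.n_spots == len(t_true)
    axis_true = _axis(t_true)
    gi = {g: i for i, g in enumerate(default_study.ds.gene_ids)}
    prof = ai.bin_profiles(
        default_study.norm[[gi[s.gene_id] for s in mid]],
        [s.gene_id for s in mid],
        axis_true,
        n_bins=20,
    )
    for gene, sub in prof.table.groupby("gene"):
        argmax = int(np.nanargmax(sub["mean"].to_numpy()))
        assert 20 / 3 <= argmax <= 2 * 20 / 3
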