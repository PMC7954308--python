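"""Rate matrix construction: six-class expressions, reversibility, scaling."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.linalg

from multihit.frequencies import NT_INDEX, codon_frequencies
from multihit.genetic_code import count_substitution_classes
from multihit.ratematrix import (
    MODEL_SPECS,
    THETA_SLOT,
    ModelParams,
    TransitionKernel,
    build_rate_matrix,
    normalize_matrices,
)


def theta_of(params, x, y):
    return params.theta[THETA_SLOT[(x, y)]]


class TestRateExpressions:
    def test_single_hit_synonymous_entry(self, universal, rich_params):
        # ACA -> ACT: theta_AT * pi_T at position 3
        rm = build_rate_matrix(rich_params, MODEL_SPECS["3H+"], 0, universal)
        i, j = universal.index("ACA"), universal.index("ACT")
        expected = theta_of(rich_params, "A", "T") * rich_params.pi.pi[2, NT_INDEX["T"]]
        assert rm.Q[i, j] == pytest.approx(expected, rel=1e-12)

    def test_double_hit_nonsynonymous_entry(self, universal, rich_params):
        # AAA -> ACC: delta * omega_k * theta_AC^2 * pi_C2 * pi_C3
        k = 1
        rm = build_rate_matrix(rich_params, MODEL_SPECS["3H+"], k, universal)
        i, j = universal.index("AAA"), universal.index("ACC")
        pi = rich_params.pi.pi
        expected = (
            rich_params.delta
            * rich_params.omega[k]
            * theta_of(rich_params, "A", "C") ** 2
            * pi[1, NT_INDEX["C"]]
            * pi[2, NT_INDEX["C"]]
        )
        assert rm.Q[i, j] == pytest.approx(expected, rel=1e-12)

    def test_triple_hit_synonymous_uses_psi_s(self, universal, rich_params):
        # AGC -> TCA: psi_s * theta_AT theta_GC theta_CA * pi_T1 pi_C2 pi_A3
        rm = build_rate_matrix(rich_params, MODEL_SPECS["3H+"], 0, universal)
        i, j = universal.index("AGC"), universal.index("TCA")
        pi = rich_params.pi.pi
        expected = (
            rich_params.psi_s
            * theta_of(rich_params, "A", "T")
            * theta_of(rich_params, "G", "C")
            * theta_of(rich_params, "C", "A")
            * pi[0, NT_INDEX["T"]]
            * pi[1, NT_INDEX["C"]]
            * pi[2, NT_INDEX["A"]]
        )
        assert rm.Q[i, j] == pytest.approx(expected, rel=1e-12)

    def test_reduction_to_single_hit_model(self, universal, rich_params):
        """3H+ with all MH rates zero is entrywise identical to 1H."""
        p0 = replace(rich_params, delta=0.0, psi_s=0.0, psi=0.0)
        q_full = build_rate_matrix(p0, MODEL_SPECS["3H+"], 1, universal).Q
        q_1h = build_rate_matrix(p0, MODEL_SPECS["1H"], 1, universal).Q
        np.testing.assert_array_equal(q_full, q_1h)

    def test_structural_sparsity(self, universal, rich_params):
        counts = count_substitution_classes(universal)
        q_full = build_rate_matrix(rich_params, MODEL_SPECS["3H+"], 0, universal).Q
        off = q_full.copy()
        np.fill_diagonal(off, 0.0)
        assert (off > 0).sum() == sum(counts.values())
        p1h = replace(rich_params, delta=0.0, psi_s=0.0, psi=0.0)
        q_1h = build_rate_matrix(p1h, MODEL_SPECS["1H"], 0, universal).Q
        off = q_1h.copy()
        np.fill_diagonal(off, 0.0)
        assert (off > 0).sum() == counts[(1, True)] + counts[(1, False)]


class TestMatrixProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_detailed_balance_and_row_sums(self, universal, rich_params, seed):
        r = np.random.default_rng(seed)
        params = replace(
            rich_params,
            theta=np.insert(r.uniform(0.2, 3.0, 5), 1, 1.0),
            delta=r.uniform(0, 2),
            psi_s=r.uniform(0, 5),
            psi=r.uniform(0, 2),
        )
        f = codon_frequencies(params.pi, universal)
        Q = build_rate_matrix(params, MODEL_SPECS["3H+"], 0, universal).Q
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        flux = f[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_normalization_unit_flux(self, universal, rich_params):
        f = codon_frequencies(rich_params.pi, universal)
        mats = [
            build_rate_matrix(rich_params, MODEL_SPECS["3H+"], k, universal)
            for k in range(3)
        ]
        scaled, s = normalize_matrices(mats, rich_params.weights, f)
        flux = sum(
            w * -(f * np.diag(Q)).sum()
            for w, Q in zip(rich_params.weights, scaled)
        )
        assert flux == pytest.approx(1.0, abs=1e-10)
        assert s > 0

    def test_degenerate_model_rejected(self, universal, rich_params):
        dead = replace(
            rich_params,
            theta=np.zeros(6), delta=0.0, psi_s=0.0, psi=0.0,
        )
        mats = [
            build_rate_matrix(dead, MODEL_SPECS["3H+"], k, universal)
            for k in range(3)
        ]
        f = codon_frequencies(dead.pi, universal)
        with pytest.raises(ValueError):
            normalize_matrices(mats, dead.weights, f)

    @pytest.mark.parametrize("t", [0.0, 0.05, 0.5, 2.0, 10.0])
    def test_transition_rows_sum_to_one(self, universal, rich_params, t):
        kernel = TransitionKernel(rich_params, MODEL_SPECS["3H+"], universal)
        P = kernel.transition(t, 2)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-9
        assert P.min() >= 0.0

    def test_eigen_route_matches_expm(self, universal, rich_params):
        kernel = TransitionKernel(rich_params, MODEL_SPECS["3H+"], universal)
        for k, t in ((0, 0.3), (2, 1.7)):
            direct = scipy.linalg.expm(kernel.Q[k] * t)
            assert np.abs(kernel.transition(t, k) - direct).max() < 1e-8

    def test_similarity_transform_symmetric(self, universal, rich_params):
        kernel = TransitionKernel(rich_params, MODEL_SPECS["3H+"], universal)
        f = kernel.freqs
        for Q in kernel.Q:
            B = np.sqrt(f)[:, None] * Q / np.sqrt(f)[None, :]
            assert np.abs(B - B.T).max() < 1e-9

    def test_mito_code_matrix(self, mito, rich_params):
        kernel = TransitionKernel(rich_params, MODEL_SPECS["3H+"], mito)
        assert kernel.Q[0].shape == (60, 60)
        P = kernel.transition(0.4, 0)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-9


class TestModelSpecs:
    def test_parameter_layout(self):
        assert MODEL_SPECS["1H"].n_mh_free == 0
        assert MODEL_SPECS["2H"].n_mh_free == 1
        assert MODEL_SPECS["3HSI"].n_mh_free == 2
        assert MODEL_SPECS["3H"].n_mh_free == 2
        assert MODEL_SPECS["3H+"].n_mh_free == 3

    def test_spec_validation(self, rich_params):
        with pytest.raises(ValueError):
            rich_params.validate_against(MODEL_SPECS["1H"])
        rich_params.validate_against(MODEL_SPECS["3H+"])
        tied = replace(rich_params, psi_s=rich_params.psi)
        tied.validate_against(MODEL_SPECS["3H"])

    def test_params_roundtrip(self, rich_params):
        d = rich_params.to_dict()
        back = ModelParams.from_dict(d)
        assert np.allclose(back.theta, rich_params.theta)
        assert np.allclose(back.omega, rich_params.omega)
        assert back.delta == rich_params.delta
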