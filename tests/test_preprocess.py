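"""High-binder weighting and the composition model."""

import numpy as np
import pytest

from epibind.array_io import BindingTable
from epibind.preprocess import (
    CompositionModel,
    WeightingConfig,
    add_composition,
    composition_matrix,
    fit_composition,
    predict_composition,
    subtract_composition,
    weight_expand,
)

CONCS = (0.125, 0.5, 2.0, 8.0)


def simulate_expansion(values, cfg):
    """Independent oracle: literal materialized copying per the stated
    rules (grow each small bin to 300 by random copies, cap 100/pair)."""
    rng = np.random.default_rng(cfg.seed)
    bins = np.floor((np.asarray(values) - cfg.bin_anchor) / cfg.bin_width).astype(int)
    totals = {}
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        copies = {int(i): 1 for i in members}
        while sum(copies.values()) < cfg.min_bin_count and any(
            v < cfg.max_copies_per_pair for v in copies.values()
        ):
            pick = int(members[rng.integers(0, len(members))])
            if copies[pick] < cfg.max_copies_per_pair:
                copies[pick] += 1
        totals[int(b)] = sum(copies.values())
    return totals


class TestWeighting:
    def test_large_bin_unchanged(self):
        values = np.full(400, 2.95)
        mult = weight_expand(values, WeightingConfig(seed=0))
        assert (mult == 1).all()

    def test_small_bin_grows_to_300(self):
        values = np.full(150, 3.11)
        mult = weight_expand(values, WeightingConfig(seed=0))
        assert mult.sum() == 300
        assert (mult >= 1).all()

    def test_two_member_bin_caps_at_200(self):
        """Copy cap (100) binds before the bin target (300): 2 pairs -> 200."""
        values = np.array([4.51, 4.55])
        mult = weight_expand(values, WeightingConfig(seed=0))
        assert mult.tolist() == [100, 100]

    def test_total_matches_min_max_formula(self):
        cfg = WeightingConfig(seed=5)
        rng = np.random.default_rng(2)
        values = rng.uniform(2.8, 4.8, size=800)
        mult = weight_expand(values, cfg)
        bins = np.floor(values / cfg.bin_width).astype(int)
        for b in np.unique(bins):
            members = bins == b
            n = members.sum()
            expected = n if n >= 300 else min(max(n, 300), 100 * n)
            assert mult[members].sum() == expected

    def test_matches_literal_copy_oracle(self):
        cfg = WeightingConfig(seed=9)
        rng = np.random.default_rng(3)
        values = np.concatenate([
            rng.uniform(2.9, 3.1, 350),   # large bins
            rng.uniform(3.9, 4.1, 40),    # mid bin -> 300
            rng.uniform(4.7, 4.75, 2),    # tiny bin -> 200
        ])
        mult = weight_expand(values, cfg)
        oracle = simulate_expansion(values, cfg)
        bins = np.floor(values / cfg.bin_width).astype(int)
        got = {int(b): int(mult[bins == b].sum()) for b in np.unique(bins)}
        assert got == oracle

    def test_deterministic_and_empty(self):
        cfg = WeightingConfig(seed=1)
        values = np.random.default_rng(0).uniform(2.9, 4.9, 100)
        assert (weight_expand(values, cfg) == weight_expand(values, cfg)).all()
        assert weight_expand(np.array([]), cfg).size == 0


def random_sequences(n, rng, lengths=(5, 11)):
    letters = np.array(list("ADEFGHKLNPQRSVWY"))
    return [
        "".join(letters[rng.integers(0, 16, rng.integers(lengths[0], lengths[1] + 1))])
        for _ in range(n)
    ]


class TestComposition:
    def test_exact_recovery_of_composition_function(self):
        rng = np.random.default_rng(4)
        seqs = random_sequences(200, rng)
        w_counts = np.array([s.count("W") for s in seqs], dtype=float)
        targets = np.tile((0.1 * w_counts + 2.9)[:, None], (1, 4))
        model = fit_composition(seqs, targets)
        w_idx = "ADEFGHKLNPQRSVWY".index("W")
        assert model.coefficients[:, w_idx] == pytest.approx(np.full(4, 0.1), abs=1e-8)
        assert model.intercepts == pytest.approx(np.full(4, 2.9), abs=1e-8)
        others = np.delete(model.coefficients, w_idx, axis=1)
        assert others == pytest.approx(np.zeros_like(others), abs=1e-8)
        resid = targets - predict_composition(model, seqs)
        assert resid == pytest.approx(np.zeros_like(resid), abs=1e-8)
        assert model.r_squared == pytest.approx(np.ones(4))

    def test_permuted_targets_give_near_zero_r2(self):
        rng = np.random.default_rng(5)
        seqs = random_sequences(2000, rng)
        w_counts = np.array([s.count("W") for s in seqs], dtype=float)
        targets = np.tile((0.1 * w_counts + 2.9)[:, None], (1, 4))
        permuted = targets[rng.permutation(len(seqs))]
        model = fit_composition(seqs, permuted)
        assert (model.r_squared < 0.05).all()

    def test_parameter_recovery_from_synthetic_landscape(self):
        """Motif-free landscape with dominant composition signal: the OLS
        fit recovers the generator's coefficients."""
        from epibind.array_io import average_replicates
        from epibind.synthetic import SyntheticLandscape, simulate_binding

        rng = np.random.default_rng(6)
        seqs = random_sequences(1500, rng)
        truth = {"W": 0.12, "Y": 0.08, "R": 0.05}
        ls = SyntheticLandscape(
            motif="PLEEV",
            match_energy=(0.0,) * 5,
            composition_coeffs=truth,
            gain=1e6,  # signal >> baseline so log counts are linear in composition
            noise_sigma=0.01,
            saturation_cap=10**9,
            seed=7,
        )
        bt = average_replicates(simulate_binding(ls, seqs))
        model = fit_composition(bt.sequences, bt.values)
        for aa, coeff in truth.items():
            idx = "ADEFGHKLNPQRSVWY".index(aa)
            assert model.coefficients[:, idx] == pytest.approx(
                np.full(4, coeff), abs=0.01
            )

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        seqs = random_sequences(300, rng)
        targets = rng.normal(3.0, 0.5, size=(300, 4))
        model = fit_composition(seqs, targets)
        resid = targets - predict_composition(model, seqs)
        X = composition_matrix(seqs)
        assert np.abs(X.T @ resid).max() < 1e-8
        assert np.abs(resid.sum(axis=0)).max() < 1e-8  # intercept column

    def test_subtract_add_round_trip(self):
        rng = np.random.default_rng(9)
        seqs = random_sequences(100, rng)
        table = BindingTable(
            sequences=seqs,
            concentrations=CONCS,
            values=rng.normal(3.0, 0.5, size=(100, 4)),
        )
        model = fit_composition(seqs, table.values)
        resid = subtract_composition(model, table)
        assert np.abs(resid.values.mean(axis=0)).max() < 1e-10
        back = add_composition(model, resid)
        assert np.abs(back.values - table.values).max() < 1e-10

    def test_zero_model_is_identity(self):
        rng = np.random.default_rng(10)
        seqs = random_sequences(20, rng)
        table = BindingTable(
            sequences=seqs, concentrations=CONCS, values=np.full((20, 4), 3.0)
        )
        zero = CompositionModel(coefficients=np.zeros((4, 16)), intercepts=np.zeros(4))
        out = subtract_composition(zero, table)
        assert out.values == pytest.approx(table.values)

    def test_single_residue_type_prediction(self):
        model = CompositionModel(
            coefficients=np.tile(np.arange(16, dtype=float) / 100, (4, 1)),
            intercepts=np.full(4, 2.9),
        )
        pred = predict_composition(model, ["WWWWW"])
        w_idx = "ADEFGHKLNPQRSVWY".index("W")
        assert pred[0] == pytest.approx(2.9 + 5 * w_idx / 100)

    def test_json_round_trip(self):
        rng = np.random.default_rng(11)
        seqs = random_sequences(100, rng)
        model = fit_composition(seqs, rng.normal(3, 0.4, (100, 4)))
        back = CompositionModel.from_json(model.to_json())
        assert back.coefficients == pytest.approx(model.coefficients)
        assert back.intercepts == pytest.approx(model.intercepts)

    def test_pooled_fit_shares_coefficients(self):
        rng = np.random.default_rng(12)
        seqs = random_sequences(400, rng)
        w = np.array([s.count("W") for s in seqs], dtype=float)
        targets = np.tile((0.2 * w + 3.0)[:, None], (1, 4))
        model = fit_composition(seqs, targets, pooled=True)
        assert (model.coefficients == model.coefficients[0]).all()
        assert (model.intercepts == model.intercepts[0]).all()
        w_idx = "ADEFGHKLNPQRSVWY".index("W")
        assert model.coefficients[0, w_idx] == pytest.approx(0.2, abs=1e-8)

    def test_rank_deficient_warns(self):
        seqs = ["AAAAA", "AAAAAA", "AAAAAAA"]  # composition spans 1 dimension
        with pytest.warns(UserWarning, match="rank deficient"):
            fit_composition(seqs, np.full((3, 4), 3.0))
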