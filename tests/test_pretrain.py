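"""Masked-feature corruption and the reconstruction objective."""

import numpy as np
import pytest

from epipoint.checkpoint import load_checkpoint, save_checkpoint
from epipoint.encoder import EncoderConfig
from epipoint.features import ResidueFeatureMatrix
from epipoint.nn import Tensor
from epipoint.pretrain import (MaskingSpec, PretrainConfig, PretrainLossWeights,
                               PretrainModel, chain_inputs_from_features,
                               corrupt, pretrain_loss, run_pretraining,
                               sample_mask)
from epipoint.rhem import RhemConfig


def random_features(rng, n=12):
    aa = np.zeros((n, 20))
    aa[np.arange(n), rng.integers(0, 20, n)] = 1.0
    comp = rng.random((n, 20))
    comp /= comp.sum(axis=1, keepdims=True)
    return ResidueFeatureMatrix(aa, rng.random((n, 20)), rng.random((n, 2)), comp)


def test_mask_fraction_extremes(rng):
    assert len(sample_mask(50, MaskingSpec(mask_fraction=0.0), rng)) == 0
    assert len(sample_mask(50, MaskingSpec(mask_fraction=1.0), rng)) == 50


def test_masking_spec_probabilities_must_be_complementary():
    with pytest.raises(ValueError):
        MaskingSpec(zero_fill_prob=0.3, random_fill_prob=0.8)


def test_masked_fraction_concentrates_at_one_half(rng):
    spec = MaskingSpec()
    total = 200_000
    n_masked = sum(len(sample_mask(1000, spec, rng)) for _ in range(total // 1000))
    assert abs(n_masked / total - 0.5) < 0.01


def test_corruption_touches_only_masked_target_blocks(rng):
    features = random_features(rng, n=40)
    mask = sample_mask(40, MaskingSpec(), rng)
    batch = corrupt(features, mask, MaskingSpec(), rng)
    unmasked = np.setdiff1d(np.arange(40), mask)
    out = batch.corrupted
    assert np.array_equal(out.aa_type[unmasked], features.aa_type[unmasked])
    assert np.array_equal(out.pssm[unmasked], features.pssm[unmasked])
    assert np.array_equal(out.solvent_acc[unmasked], features.solvent_acc[unmasked])
    # neighbour composition is never a corruption target
    assert np.array_equal(out.neighbor_comp, features.neighbor_comp)
    # masked rows are either jointly zero or a valid random refill
    for j in mask:
        zeroed = (out.aa_type[j].sum() == 0)
        if zeroed:
            assert out.solvent_acc[j].sum() == 0 and out.pssm[j].sum() == 0
        else:
            assert out.aa_type[j].sum() == 1.0
            assert ((0 <= out.pssm[j]) & (out.pssm[j] <= 1)).all()


def test_zero_fill_rate_concentrates_at_one_fifth(rng):
    spec = MaskingSpec()
    features = random_features(rng, n=1000)
    n_zero, n_masked = 0, 0
    while n_masked < 100_000:
        mask = np.arange(1000)  # corrupt every residue to count fill choices
        out = corrupt(features, mask, spec, rng).corrupted
        n_zero += int(np.sum(out.aa_type.sum(axis=1) == 0))
        n_masked += 1000
    assert abs(n_zero / n_masked - 0.20) < 0.01


@pytest.fixture
def tiny_model(tiny_rhem_cfg, tiny_enc_cfg):
    return PretrainModel(tiny_rhem_cfg, tiny_enc_cfg,
                         np.random.default_rng(0), head_dropout=0.0).eval()


def test_reconstruction_heads(tiny_model, rng):
    from epipoint.rhem import ChainInputs

    inputs = ChainInputs(rng.normal(size=(5, 11)), np.array([0, 2, 4]),
                         rng.random((3, 62)))
    aa, sol, pssm = tiny_model(inputs)
    assert aa.shape == (3, 20) and sol.shape == (3, 2) and pssm.shape == (3, 20)
    aa2, _, _ = tiny_model(inputs)
    assert np.array_equal(aa.data, aa2.data)  # eval determinism
    ids = [set(id(p) for p in head.parameters())
           for head in (tiny_model.head_aa, tiny_model.head_sol,
                        tiny_model.head_pssm)]
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])


def test_perfect_predictions_zero_regression_loss(rng):
    features = random_features(rng, n=6)
    mask = np.array([1, 3])
    saturated = Tensor(features.aa_type * 1000.0)
    preds = (saturated, Tensor(features.solvent_acc), Tensor(features.pssm))
    total, comps = pretrain_loss(preds, features, mask)
    assert comps["sol"] == 0.0 and comps["pssm"] == 0.0
    assert comps["aa"] < 1e-6  # CE at saturated correct logits


def test_empty_mask_gives_zero_loss(rng):
    features = random_features(rng)
    preds = (Tensor(np.zeros((12, 20))), Tensor(np.zeros((12, 2))),
             Tensor(np.zeros((12, 20))))
    total, comps = pretrain_loss(preds, features, np.array([], dtype=int))
    assert float(total.data) == 0.0


def test_uniform_logits_cross_entropy_is_log_twenty(rng):
    features = random_features(rng, n=2)
    mask = np.array([0, 1])
    preds = (Tensor(np.zeros((2, 20))), Tensor(features.solvent_acc),
             Tensor(features.pssm))
    _, comps = pretrain_loss(preds, features, mask)
    assert comps["aa"] == pytest.approx(np.log(20), abs=1e-9)


def test_loss_is_linear_in_lambda_weights(rng):
    features = random_features(rng)
    mask = np.array([0, 4, 7])
    preds = (Tensor(rng.normal(size=(12, 20))), Tensor(rng.random((12, 2))),
             Tensor(rng.random((12, 20))))
    base, comps = pretrain_loss(preds, features, mask, PretrainLossWeights())
    doubled, _ = pretrain_loss(preds, features, mask,
                               PretrainLossWeights(lambda_aa=2.0))
    assert float(doubled.data) - float(base.data) == pytest.approx(comps["aa"])


def test_loss_gradient_zero_at_unmasked_predictions(rng):
    features = random_features(rng)
    mask = np.array([2, 5])
    preds = tuple(Tensor(rng.normal(size=s), requires_grad=True)
                  for s in [(12, 20), (12, 2), (12, 20)])
    total, _ = pretrain_loss(preds, features, mask)
    total.backward()
    unmasked = np.setdiff1d(np.arange(12), mask)
    for p in preds:
        assert np.all(p.grad[unmasked] == 0.0)
        assert np.any(p.grad[mask] != 0.0)


def test_checkpoint_round_trip_reproduces_loss_bitwise(tiny_rhem_cfg,
                                                       tiny_enc_cfg, tmp_path,
                                                       rng):
    from epipoint.rhem import ChainInputs

    model = PretrainModel(tiny_rhem_cfg, tiny_enc_cfg,
                          np.random.default_rng(3), head_dropout=0.0).eval()
    inputs = ChainInputs(rng.normal(size=(6, 11)), np.array([0, 3]),
                         rng.random((2, 62)))
    features = random_features(rng, n=2)
    mask = np.array([0, 1])
    loss1, _ = pretrain_loss(model(inputs), features, mask)
    save_checkpoint(tmp_path / "ck.npz", model, meta={"stage": "pretrain"})
    state, meta = load_checkpoint(tmp_path / "ck.npz")
    assert meta["stage"] == "pretrain"
    clone = PretrainModel(tiny_rhem_cfg, tiny_enc_cfg,
                          np.random.default_rng(999), head_dropout=0.0).eval()
    clone.load_state_dict(state)
    loss2, _ = pretrain_loss(clone(inputs), features, mask)
    assert float(loss1.data) == float(loss2.data)  # bit-for-bit


def test_run_pretraining_logs_finite_decreasing_loss(small_spec):
    from epipoint.synthetic import generate_dataset

    data = generate_dataset(small_spec.__class__(
        n_complexes=2, antigen_residues=(15, 20), antibody_residues=(10, 14),
        rng_seed=5))
    log = []
    model = PretrainModel(
        RhemConfig(atom_mlp_widths=(11, 8, 16), d_model=16, dropout=0.0),
        EncoderConfig(n_blocks=2, d_model=16, n_heads=2, dropout=0.0),
        np.random.default_rng(0))
    run_pretraining(data, PretrainConfig(epochs=3, warmup_epochs=1,
                                         batch_size=2, seed=2),
                    model=model, log=log)
    losses = [row["loss"] for row in log]
    assert all(np.isfinite(losses))
    assert len(losses) == 3 * 2 * 2  # epochs x complexes x chains
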