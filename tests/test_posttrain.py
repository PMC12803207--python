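"""Input construction, balancing, EMA teacher, and the alignment objective."""

import numpy as np
import pytest

from cellstack.io_core import CellSet
from cellstack.model import ModelConfig, StackModel
from cellstack.nn import AdamW
from cellstack.posttrain import (EmaTeacher, PosttrainConfig, balance_cell_types,
                                 build_prompted_input, ema_update,
                                 posttrain_losses, posttrain_step)
from cellstack.simulate import SimConfig, simulate_cohort

from conftest import make_cellset


def _typed_cells(rng, counts_by_type, g=30):
    rows, types = [], []
    for t, n in counts_by_type.items():
        rows.append(rng.poisson(4.0, size=(n, g)) + 1)
        types += [t] * n
    return make_cellset(np.vstack(rows), cell_type=np.array(types, dtype=object))


class TestBalancing:
    def test_direct_rule_application(self, rng):
        cells = _typed_cells(rng, {"A": 6, "B": 2})
        out, first = balance_cell_types(cells, rng)
        assert out.n_cells == 8
        assert first.sum() == 6  # pool of 4 + 2, two duplicate copies flagged
        _, counts = np.unique(out.cell_type[first].astype(str), return_counts=True)
        assert sorted(counts) == [2, 4]

    def test_already_balanced_is_fixed_point(self, rng):
        cells = _typed_cells(rng, {"A": 4, "B": 4})
        out, first = balance_cell_types(cells, rng)
        assert out.n_cells == 8 and first.all()
        assert sorted(out.cell_ids) == sorted(cells.cell_ids)

    def test_upsampling_preserves_pool_proportions(self):
        """Over many seeds, the expected minority fraction after balancing
        equals its pool fraction (10 of 60)."""
        rng = np.random.default_rng(0)
        cells = _typed_cells(np.random.default_rng(1), {"A": 90, "B": 10})
        fracs = []
        for s in range(1000):
            out, _ = balance_cell_types(cells, np.random.default_rng(s))
            fracs.append(np.mean(out.cell_type.astype(str) == "B"))
        assert abs(np.mean(fracs) - 10 / 60) < 0.01

    def test_single_cell_returned_unchanged(self, rng):
        cells = _typed_cells(rng, {"A": 1})
        out, first = balance_cell_types(cells, rng)
        assert out.n_cells == 1 and first.all()


@pytest.fixture(scope="module")
def toy_world():
    cfg = SimConfig(n_genes=30, n_cell_types=3, n_donors=2, n_conditions=2,
                    cells_per_sample=64, libsize_logmean=5.0, seed=13)
    sets, truth = simulate_cohort(cfg)
    prompt = next(s for s in sets if s.sample_id == "donor0_cond1")
    query_pool = next(s for s in sets if s.sample_id == "donor1_control")
    model_cfg = ModelConfig(n_genes=30, n_layers=1, n_tokens=4, token_dim=4,
                            heads_intra=2, heads_inter=4)
    student = StackModel(model_cfg, rng=np.random.default_rng(3))
    teacher = EmaTeacher(model=StackModel(model_cfg, rng=np.random.default_rng(3)),
                         decay=0.95, update_interval=10)
    return prompt, query_pool, student, teacher


class TestPromptedInput:
    def test_partition_arithmetic_k512(self, rng):
        cells = _typed_cells(np.random.default_rng(2), {"A": 200, "B": 200, "C": 112})
        model = StackModel(ModelConfig(n_genes=30, n_layers=1, n_tokens=2,
                                       token_dim=4, heads_intra=2, heads_inter=4),
                           rng=np.random.default_rng(0))
        pool = _typed_cells(np.random.default_rng(3), {"A": 300, "B": 300, "C": 300})
        pin = build_prompted_input(cells, pool, model, np.random.default_rng(4))
        k = pin.cells.n_cells
        assert k == 512
        assert (pin.roles == "prompt_condition").sum() == 128
        n_kept = (pin.roles == "prompt_context").sum()
        n_query = (pin.roles == "query").sum()
        assert n_kept + n_query == 384

    def test_type_blocks_consecutive(self, toy_world):
        prompt, pool, student, teacher = toy_world
        pin = build_prompted_input(prompt, pool, teacher.model,
                                   np.random.default_rng(5))
        types = pin.type_of.astype(str)
        changes = np.sum(types[1:] != types[:-1])
        assert changes == len(np.unique(types)) - 1

    def test_query_types_match_displaced_targets(self, toy_world):
        prompt, pool, student, teacher = toy_world
        for seed in range(5):
            pin = build_prompted_input(prompt, pool, teacher.model,
                                       np.random.default_rng(seed))
            q_types = pin.cells.cell_type[pin.query_positions].astype(str)
            t_types = pin.target.cell_type.astype(str)
            assert np.array_equal(q_types, t_types)

    def test_missing_query_type_errors(self, toy_world, rng):
        prompt, _, student, teacher = toy_world
        bad_pool = _typed_cells(np.random.default_rng(1), {"nosuchtype": 50})
        with pytest.raises(ValueError, match="no cells of type"):
            build_prompted_input(prompt, bad_pool, teacher.model,
                                 np.random.default_rng(0))

    def test_prompt_condition_cells_unchanged(self, toy_world):
        prompt, pool, student, teacher = toy_world
        pin = build_prompted_input(prompt, pool, teacher.model,
                                   np.random.default_rng(6))
        n_cond = int(round(0.25 * pin.cells.n_cells))
        assert np.array_equal(pin.cells.counts[:n_cond],
                              pin.original_cells.counts[:n_cond])


class TestEmaUpdate:
    def _scalar_models(self, t_val, s_val):
        cfg = ModelConfig(n_genes=4, n_layers=1, n_tokens=1, token_dim=2,
                          heads_intra=1, heads_inter=2)
        teacher = EmaTeacher(model=StackModel(cfg, rng=np.random.default_rng(0)),
                             decay=0.95, update_interval=1)
        student = StackModel(cfg, rng=np.random.default_rng(0))
        for p in teacher.model.parameters():
            p.data[:] = t_val
        state = student.state_dict()
        for k in state:
            state[k][:] = s_val
        return teacher, state

    @pytest.mark.parametrize("decay,expected", [(1.0, 0.0), (0.0, 1.0), (0.95, 0.05)])
    def test_blend_arithmetic(self, decay, expected):
        teacher, state = self._scalar_models(0.0, 1.0)
        teacher.decay = decay
        ema_update(teacher, state)
        for p in teacher.model.parameters():
            assert np.allclose(p.data, expected)

    def test_interval_gating(self):
        teacher, state = self._scalar_models(0.0, 1.0)
        teacher.update_interval = 500
        ema_update(teacher, state, step=499)  # not a multiple: no-op
        assert all(np.all(p.data == 0) for p in teacher.model.parameters())
        ema_update(teacher, state, step=500)
        assert all(np.allclose(p.data, 0.05) for p in teacher.model.parameters())

    def test_shape_mismatch_rejected(self):
        teacher, state = self._scalar_models(0.0, 1.0)
        bad = {k: v[..., :1] for k, v in state.items()}
        with pytest.raises(ValueError):
            ema_update(teacher, bad)


class TestPosttrainStep:
    def test_lambda_zero_total_is_dist(self, toy_world):
        prompt, pool, student, teacher = toy_world
        pin = build_prompted_input(prompt, pool, teacher.model,
                                   np.random.default_rng(7))
        cfg = PosttrainConfig(lambda_recon=0.0, lambda_sw=0.0, lambda_cls=0.0,
                              sw_subset_range=(8, 16))
        total, rep = posttrain_losses(student, teacher, pin, cfg,
                                      np.random.default_rng(8))
        assert np.isclose(rep.total, rep.dist)
        assert np.isclose(rep.dist, 0.5 * (rep.gene + rep.embed))

    def test_config_mismatch_rejected(self, toy_world):
        prompt, pool, student, _ = toy_world
        other = EmaTeacher(model=StackModel(
            ModelConfig(n_genes=30, n_layers=2, n_tokens=4, token_dim=4,
                        heads_intra=2, heads_inter=4), rng=np.random.default_rng(0)))
        pin = build_prompted_input(prompt, pool, student, np.random.default_rng(9))
        with pytest.raises(ValueError, match="config"):
            posttrain_losses(student, other, pin, PosttrainConfig(),
                             np.random.default_rng(0))

    def test_duplicate_exclusion_changes_distributional_loss(self, rng):
        """The first-instance path is live: computing L_embed with duplicates
        included gives a different value than the implementation's."""
        from cellstack._autograd import Tensor
        from cellstack.posttrain import _stratified_energy

        emb = rng.normal(size=(6, 8))
        types = np.array(["A"] * 6)
        all_idx = np.arange(6)
        first = np.array([True, True, True, True, False, False])
        a = _stratified_energy(Tensor(emb[first]), Tensor(emb[first] + 1.0),
                               types[first], types[first], 2).item()
        b = _stratified_energy(Tensor(emb), Tensor(emb + 1.0), types, types, 2).item()
        assert not np.isclose(a, b)

    def test_one_step_runs_and_reports_finite(self, toy_world):
        prompt, pool, student, teacher = toy_world
        pin = build_prompted_input(prompt, pool, teacher.model,
                                   np.random.default_rng(10))
        cfg = PosttrainConfig(sw_subset_range=(8, 16))
        opt = AdamW(student.parameters(), lr=1e-4)
        rep = posttrain_step(student, teacher, pin, opt, cfg,
                             np.random.default_rng(11))
        for val in (rep.total, rep.gene, rep.embed, rep.recon, rep.sw, rep.cls):
            assert np.isfinite(val)

    def test_causal_isolation_survives_posttraining(self, toy_world, rng):
        """Prompt-condition embeddings remain exactly independent of query
        contents after optimizer updates to the post-trained weights."""
        from cellstack.model import AttentionMaskSpec, build_causal_mask

        prompt, pool, _, teacher = toy_world
        student = StackModel(teacher.model.config, rng=np.random.default_rng(31))
        cfg = PosttrainConfig(sw_subset_range=(8, 16))
        opt = AdamW(student.parameters(), lr=1e-3)
        for i in range(3):
            pin = build_prompted_input(prompt, pool, teacher.model,
                                       np.random.default_rng(40 + i))
            posttrain_step(student, teacher, pin, opt, cfg,
                           np.random.default_rng(50 + i))
        counts = rng.poisson(4, size=(6, 30)) + 1
        lib = counts.sum(axis=1)
        roles = np.array(["prompt_condition"] * 2 + ["prompt_context"] * 2
                         + ["query"] * 2, dtype=object)
        mask = build_causal_mask(roles)
        emb1 = student.encode(counts, lib, roles=roles, mask=mask)
        counts2 = counts.copy()
        counts2[2:] = rng.poisson(40, size=(4, 30))
        emb2 = student.encode(counts2, lib, roles=roles, mask=mask)
        assert np.array_equal(emb1.flat.data[:2], emb2.flat.data[:2])

    def test_classifier_beats_chance_after_training(self, toy_world):
        """BCE of the prompt-context vs query classifier drops below ln 2
        after a few steps on one prompted input."""
        from cellstack.posttrain import enable_new_module_gradient_scaling

        prompt, pool, _, teacher = toy_world
        student = StackModel(teacher.model.config, rng=np.random.default_rng(21))
        enable_new_module_gradient_scaling(student)
        cfg = PosttrainConfig(sw_subset_range=(8, 16), peak_lr=3e-3)
        opt = AdamW(student.parameters(), lr=3e-3)
        rng = np.random.default_rng(12)
        rep = None
        for i in range(25):
            pin = build_prompted_input(prompt, pool, teacher.model,
                                       np.random.default_rng(13))
            rep = posttrain_step(student, teacher, pin, opt, cfg, rng)
        assert rep.cls < np.log(2)
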