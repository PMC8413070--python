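"""The FS cardinality sweep and the SFS block lattice."""

import numpy as np
import pandas as pd
import pytest

import facebeauty as fb
from facebeauty.ablation import (AblationGrid, SFS_CONFIGS, fs_ablation,
                                 select_best, sfs_ablation)
from facebeauty.dataset import BLOCK_COLUMNS, FeatureTables
from facebeauty.models import ModelSpec
from facebeauty.ratios import FEATURE_NAMES
from facebeauty.synthetic import FaceSpec, sample_face

CHEAP_SPECS = {
    "LR": ModelSpec("LR", seed=0),
    "KNN": ModelSpec("KNN", seed=0, k=5),
}


def landmark_only_tables(n=120, noise_sd=0.05, seed=0, signal="g01"):
    """Feature tables with planted signal in one golden ratio and all-zero
    descriptor blocks (cheap: no images rendered at 350x350 resolution
    beyond the landmark warp)."""
    rng = np.random.default_rng(seed)
    rows, scores = [], []
    for i in range(n):
        target = rng.uniform(1.2, 2.0)
        lm, _ = sample_face(
            FaceSpec(ratio_targets={signal: target}, asymmetry=1.0,
                     texture_noise_sd=0.0, seed=int(rng.integers(2 ** 31))),
            image_id=f"f{i:04d}")
        rows.append(fb.feature_set(lm).as_vector())
        scores.append(2.0 + 1.5 * target + rng.normal(0, noise_sd))
    ids = [f"f{i:04d}" for i in range(n)]
    zeros = lambda cols: pd.DataFrame(0.0, index=ids, columns=cols)
    return FeatureTables(
        fs=pd.DataFrame(rows, index=ids, columns=list(FEATURE_NAMES)),
        texture=zeros(BLOCK_COLUMNS["T"]),
        color=zeros([f"hsv_{c}_{k:02d}" for c in "hsv" for k in range(16)]),
        shape=zeros(BLOCK_COLUMNS["S"]),
        scores=pd.Series(scores, index=ids, name="score"),
    )


@pytest.fixture(scope="module")
def planted_tables():
    return landmark_only_tables()


class TestFsAblation:
    def test_grid_covers_all_cardinality_model_cells(self, planted_tables):
        grid = fs_ablation(planted_tables, CHEAP_SPECS, seed=0)
        assert sorted(grid.table["config"].unique()) == list(range(4, 20))
        assert set(grid.table["model"]) == set(CHEAP_SPECS)
        assert len(grid) == 16 * len(CHEAP_SPECS)

    def test_full_cardinality_equals_plain_evaluation(self, planted_tables):
        grid = fs_ablation(planted_tables, CHEAP_SPECS,
                           cardinalities=[19], seed=0)
        y = planted_tables.scores.values
        tr, te = fb.split_dataset(len(y), 0.8, 0)
        model = fb.fit(CHEAP_SPECS["LR"], planted_tables.fs.values[tr], y[tr])
        rep = fb.evaluate(y[te], model.predict(planted_tables.fs.values[te]))
        assert grid.row(19, "LR")["pc"] == pytest.approx(rep.pc)

    def test_retaining_the_signal_feature_beats_dropping_it(
            self, planted_tables):
        """At equal cardinality, orders keeping the planted ratio outperform
        orders that exclude it.  The g01 warp moves landmarks 49/57, which
        feed both g01 and g02, so the drop order must exclude both
        signal-carrying columns."""
        keep = list(FEATURE_NAMES)                      # g01, g02 first
        signal = ("g01", "g02")
        drop = [n for n in FEATURE_NAMES if n not in signal] + list(signal)
        g_keep = fs_ablation(planted_tables, {"LR": CHEAP_SPECS["LR"]},
                             removal_order=keep, cardinalities=[4], seed=0)
        g_drop = fs_ablation(planted_tables, {"LR": CHEAP_SPECS["LR"]},
                             removal_order=drop, cardinalities=[4], seed=0)
        assert g_keep.row(4, "LR")["pc"] > g_drop.row(4, "LR")["pc"] + 0.2

    def test_cardinality_out_of_range(self, planted_tables):
        with pytest.raises(ValueError):
            fs_ablation(planted_tables, CHEAP_SPECS, cardinalities=[0])
        with pytest.raises(ValueError):
            fs_ablation(planted_tables, CHEAP_SPECS, cardinalities=[31])

    def test_cardinalities_past_19_append_glcm_then_hu(self, planted_tables):
        grid = fs_ablation(planted_tables, {"LR": CHEAP_SPECS["LR"]},
                           cardinalities=[23, 30], seed=0)
        assert list(grid.table["config"]) == [23, 30]


class TestSelectBest:
    def _grid(self, rows):
        return AblationGrid(pd.DataFrame(
            rows, columns=["config", "model", "pc", "r2", "mae", "mse",
                           "n_features", "seed"]))

    def test_strictly_best_row_selected(self):
        g = self._grid([[4, "LR", 0.5, 0.2, 0.4, 0.3, 4, 0],
                        [5, "LR", 0.7, 0.4, 0.3, 0.2, 5, 0]])
        assert select_best(g, "pc") == {"LR": 5}
        assert select_best(g, "mae") == {"LR": 5}

    def test_tie_breaks_toward_fewer_features(self):
        g = self._grid([[17, "LR", 0.7, 0.4, 0.3, 0.2, 17, 0],
                        [14, "LR", 0.7, 0.4, 0.3, 0.2, 14, 0]])
        assert select_best(g, "pc") == {"LR": 14}

    def test_empty_grid_and_unknown_metric(self):
        with pytest.raises(ValueError):
            select_best(self._grid([]), "pc")
        g = self._grid([[4, "LR", 0.5, 0.2, 0.4, 0.3, 4, 0]])
        with pytest.raises(ValueError):
            select_best(g, "accuracy")


@pytest.fixture(scope="module")
def hue_tables():
    """Small hue-planted cohort with real rendered images."""
    ds = fb.make_dataset(120, "hue-only", noise_sd=0.1, seed=4)
    return fb.extract_features(ds)


class TestSfsAblation:
    def test_lattice_has_exactly_the_8_configurations(self, hue_tables):
        grid = sfs_ablation(hue_tables, CHEAP_SPECS,
                            best_fs={"LR": 14, "KNN": 14}, seed=0)
        labels = [lab for lab, _ in SFS_CONFIGS]
        assert labels == ["Without", "T + C + S", "T + C", "T + S", "C + S",
                          "T", "C", "S"]
        for m in CHEAP_SPECS:
            assert list(grid.table[grid.table["model"] == m]["config"]) \
                == labels

    def test_without_row_equals_fs_only(self, hue_tables):
        grid = sfs_ablation(hue_tables, {"LR": CHEAP_SPECS["LR"]},
                            best_fs={"LR": 19}, seed=0)
        y = hue_tables.scores.values
        tr, te = fb.split_dataset(len(y), 0.8, 0)
        model = fb.fit(CHEAP_SPECS["LR"], hue_tables.fs.values[tr], y[tr])
        rep = fb.evaluate(y[te], model.predict(hue_tables.fs.values[te]))
        assert grid.row("Without", "LR")["pc"] == pytest.approx(rep.pc)

    def test_color_block_carries_the_hue_signal(self, hue_tables):
        """Planted hue-only signal: every configuration containing C beats
        every C-free configuration on held-out PC."""
        grid = sfs_ablation(hue_tables, {"KNN": CHEAP_SPECS["KNN"]},
                            best_fs={"KNN": 19}, seed=0)
        pc = {lab: grid.row(lab, "KNN")["pc"] for lab, _ in SFS_CONFIGS}
        with_c = [v for k, v in pc.items() if "C" in k]
        without_c = [v for k, v in pc.items() if "C" not in k]
        assert min(with_c) > max(without_c)

    def test_rerun_with_same_seed_is_byte_identical(self, hue_tables,
                                                    tmp_path):
        paths = []
        for run in (1, 2):
            grid = sfs_ablation(hue_tables, CHEAP_SPECS,
                                best_fs={"LR": 14, "KNN": 14}, seed=0)
            p = tmp_path / f"grid{run}.csv"
            grid.to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
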