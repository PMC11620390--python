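import json

import numpy as np
import pandas as pd
import pytest

from tilagree.framework import compare_observer_sets, merge_observers, run_full_framework
from tilagree.io_annotations import DatasetManifest, read_report
from tilagree.model import (
    CellDetectionAgreement,
    SegmentationAgreement,
    TilsConcordance,
)
from tilagree.synthetic_data import SynthConfig, generate_dataset

SMALL = dict(height=96, width=96, pixel_size_um=1.0, length_scale=10.0,
             lymph_density_per_mm2=1500.0)


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    cfg = SynthConfig(seed=21, **SMALL)
    out = tmp_path_factory.mktemp("ds")
    return generate_dataset(cfg, 4, out)


class TestSegmentationAgreementModel:
    def test_fit_summary_and_gain(self, blob_stack):
        res = SegmentationAgreement(blob_stack, dt=50).fit()
        assert res.bwfk.kappa > res.fk.kappa
        text = res.summary()
        assert "Fleiss' kappa" in text and "BWFK gain" in text

    def test_shift_test_hangs_off_model(self, blob_stack):
        model = SegmentationAgreement(blob_stack, dt=50)
        res = model.shift_test([0, 5], seed=0)
        assert len(res.fk) == 2


class TestCellDetectionAgreementModel:
    def test_fit_from_physical_calibration(self, separated_points):
        res = CellDetectionAgreement(separated_points, pixel_size_um=0.4).fit()
        assert res.model.config.d_l == pytest.approx(20.0)
        assert res.score == 1.0
        assert "DBCAA" in res.summary()

    def test_requires_radius_or_calibration(self, separated_points):
        with pytest.raises(ValueError, match="pixel_size_um"):
            CellDetectionAgreement(separated_points)

    def test_sensitivity_methods(self, separated_points):
        model = CellDetectionAgreement(separated_points, d_l=20)
        assert model.lost_test([0.5], seed=0).scores[0] < 1.0
        assert model.shift_test([0], seed=0).scores[0] == 1.0


class TestTilsConcordanceModel:
    def test_fit_icc_and_loam(self, rng):
        quality = rng.uniform(0, 1, size=(10, 1))
        scores = pd.DataFrame(quality + rng.normal(scale=0.02, size=(10, 4)))
        res = TilsConcordance(scores).fit()
        assert res.icc.value > 0.9
        assert res.loam.upper > 0 > res.loam.lower
        assert "ICC" in res.summary()

    def test_from_annotations(self, small_dataset):
        stacks, points = [], []
        for image_id in small_dataset.image_ids:
            st, ps = small_dataset.load_image(image_id)
            stacks.append(st)
            points.append(ps)
        model = TilsConcordance.from_annotations(
            stacks, points, pixel_size_um=small_dataset.pixel_size_um
        )
        assert model.scores.shape == (4, 4)
        assert (model.scores.to_numpy() >= 0).all()


class TestRunFullFramework:
    def test_report_covers_all_measures(self, small_dataset):
        report = run_full_framework(small_dataset, seed=0)
        assert list(report.per_image.index) == small_dataset.image_ids
        for col in ("fk", "bwfk", "dbcaa"):
            assert col in report.per_image.columns
        tils_cols = [c for c in report.per_image.columns if c.startswith("tils_")]
        assert len(tils_cols) == 4
        assert "icc" in report.dataset and "loam" in report.dataset
        assert report.config["seed"] == 0

    def test_roundtrip_through_files(self, small_dataset, tmp_path):
        from tilagree.io_annotations import write_report

        report = run_full_framework(small_dataset, seed=0)
        jp, _ = write_report(report, tmp_path / "rep")
        back = read_report(jp)
        pd.testing.assert_frame_equal(back.per_image, report.per_image,
                                      atol=1e-12)


class TestCompareObserverSets:
    def test_duplicate_observer_agrees_with_twin(self, small_dataset, tmp_path):
        # the "AI" observer is a byte-for-byte copy of obs1
        import shutil
        import yaml

        root = small_dataset.root
        extra_dir = tmp_path / "extra"
        extra_dir.mkdir()
        entries = []
        for e in small_dataset.entries:
            shutil.copy(root / e.mask_paths["obs1"],
                        extra_dir / e.mask_paths["obs1"])
            shutil.copy(root / e.point_paths["obs1"],
                        extra_dir / e.point_paths["obs1"])
            entries.append({"image_id": e.image_id,
                            "masks": {"ai": e.mask_paths["obs1"]},
                            "points": {"ai": e.point_paths["obs1"]}})
        (extra_dir / "manifest.yaml").write_text(yaml.safe_dump({
            "pixel_size_um": small_dataset.pixel_size_um,
            "observers": ["ai"], "images": entries,
        }))
        extra = DatasetManifest.from_yaml(extra_dir / "manifest.yaml")
        report = compare_observer_sets(small_dataset, extra, provenance="model",
                                       seed=0)
        assert "tils_model:ai" in report.per_image.columns
        np.testing.assert_allclose(report.per_image["tils_model:ai"],
                                   report.per_image["tils_obs1"])

    def test_frame_mismatch_fatal(self, small_dataset):
        stack, points = small_dataset.load_image(small_dataset.image_ids[0])
        from tilagree.io_annotations import MaskStack

        wrong = MaskStack(masks=np.zeros((2, 10, 10), dtype=np.uint8),
                          observer_ids=["x", "y"])
        with pytest.raises(ValueError, match="frame mismatch"):
            merge_observers(stack, points, extra_stack=wrong)


class TestCli:
    def test_simulate_and_run_all(self, tmp_path):
        from typer.testing import CliRunner

        from tilagree.cli import app

        runner = CliRunner()
        ds = tmp_path / "ds"
        r = runner.invoke(app, [
            "simulate", "--out", str(ds), "--n-images", "2", "--size", "96",
            "--seed", "3",
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(app, [
            "run-all", "--manifest", str(ds / "manifest.yaml"),
            "--out", str(tmp_path / "rep"), "--seed", "1",
        ])
        assert r.exit_code == 0, r.output
        payload = json.loads((tmp_path / "rep.json").read_text())
        assert len(payload["per_image"]["index"]) == 2

    def test_agree_stroma_json(self, tmp_path):
        from typer.testing import CliRunner

        from tilagree.cli import app

        runner = CliRunner()
        ds = tmp_path / "ds"
        cfg = SynthConfig(seed=5, **SMALL)
        generate_dataset(cfg, 1, ds)
        out = tmp_path / "fk.json"
        r = runner.invoke(app, [
            "agree-stroma", "--manifest", str(ds / "manifest.yaml"),
            "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        payload = json.loads(out.read_text())
        img = payload["images"]["img000"]
        assert 0 <= img["bwfk"] <= 1
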