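"""Feature alignment, inference on query matrices, archives and the CLI."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

from citegate.cli import run
from citegate.containers import CountMatrix
from citegate.features import FeatureSet
from citegate.inference import ArchiveError, TrainedModel, align_features, infer
from citegate.model import MarkerModel
from citegate.synthetic import SimConfig, simulate


@pytest.fixture(scope="module")
def fitted():
    """A quickly trained (non-optimized) model on planted-signal data."""
    from citegate.classifiers import HyperParams

    cm, adt, truth = simulate(SimConfig(n_cells=900, n_genes=300, seed=5))
    model = MarkerModel(cm, adt)
    hp = HyperParams(model_kind="svm_rbf", t_de_upper=1.5, t_de_lower=-1.5,
                     p_hn=0.05, c_svm=10.0, gamma=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = model.fit("svm_rbf", optimize=False, hp=hp, seed=42)
    return cm, adt, truth, results


class TestAlignFeatures:
    def setup_method(self):
        self.fs = FeatureSet(genes=[f"G{i}" for i in range(10)])

    def test_shuffled_columns_realigned(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 10))
        perm = rng.permutation(10)
        genes = np.array([f"G{i}" for i in range(10)])[perm]
        out = align_features(values[:, perm], genes, self.fs)
        assert np.array_equal(out, values)

    def test_single_missing_gene_zero_filled_with_warning(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 9))
        genes = [f"G{i}" for i in range(9)]
        with pytest.warns(UserWarning, match="zero-filled"):
            out = align_features(values, genes, self.fs)
        assert np.all(out[:, 9] == 0.0)

    def test_too_many_missing_errors(self):
        values = np.zeros((5, 4))
        with pytest.raises(ValueError, match="feature space mismatch"):
            align_features(values, ["G0", "G1", "G2", "G3"], self.fs)


class TestInfer:
    def test_training_matrix_reproduces_training_accuracy(self, fitted):
        cm, adt, truth, results = fitted
        trained = results.to_trained_model()
        pred = infer(trained, results.model._m_labeled)
        y = results.model._y
        acc = ((pred["label"] == "positive").to_numpy().astype(int) == y).mean()
        assert acc == pytest.approx(
            trained.metadata["training_accuracy"], abs=0.02
        )

    def test_duplicated_cells_get_identical_predictions(self, fitted):
        cm, _, _, results = fitted
        trained = results.to_trained_model()
        sub = cm.subset_cells(np.arange(50))
        dup = CountMatrix(
            np.vstack([sub.dense(), sub.dense()]),
            sub.gene_ids,
            [f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)],
        )
        pred = infer(trained, dup)
        assert np.array_equal(pred["score"].to_numpy()[:50], pred["score"].to_numpy()[50:])

    def test_all_negative_validation_set(self, fitted):
        """Cells simulated from the negative class only are called negative."""
        cm, _, _, results = fitted
        trained = results.to_trained_model()
        neg_cm, _, neg_truth = simulate(
            SimConfig(n_cells=600, n_genes=300, seed=6, frac_positive=0.001)
        )
        keep = neg_truth.is_positive == 0
        pred = infer(trained, neg_cm.subset_cells(keep))
        assert (pred["label"] == "negative").mean() >= 0.95

    def test_archive_round_trip_bit_identical(self, fitted, tmp_path):
        cm, _, _, results = fitted
        trained = results.to_trained_model()
        query, _, _ = simulate(SimConfig(n_cells=1000, n_genes=300, seed=8))
        before = infer(trained, query)
        path = tmp_path / "model.zip"
        trained.save(path)
        loaded = TrainedModel.load(path)
        after = infer(loaded, query)
        assert np.array_equal(before["score"].to_numpy(), after["score"].to_numpy())
        assert before["label"].tolist() == after["label"].tolist()

    def test_truncated_archive_rejected(self, fitted, tmp_path):
        _, _, _, results = fitted
        path = tmp_path / "model.zip"
        results.save(path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ArchiveError, match="hash mismatch"):
            TrainedModel.load(path)

    def test_tampered_member_rejected(self, fitted, tmp_path):
        import zipfile

        _, _, _, results = fitted
        path = tmp_path / "model.zip"
        results.save(path)
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            contents = {n: zf.read(n) for n in names}
        contents["featureset.json"] = contents["featureset.json"].replace(b"G", b"X", 1)
        with zipfile.ZipFile(path, "w") as zf:
            for n, data in contents.items():
                zf.writestr(n, data)
        with pytest.raises(ArchiveError, match="manifest hash mismatch"):
            TrainedModel.load(path)


class TestCli:
    @pytest.fixture(scope="class")
    def pipeline_dir(self, tmp_path_factory):
        """simulate -> train -> predict -> evaluate, all through the CLI."""
        root = tmp_path_factory.mktemp("cli")
        sim = root / "sim"
        assert run(["simulate", "--out", str(sim), "--seed", "3",
                    "--n-cells", "700", "--n-genes", "300"]) == 0
        assert run([
            "train", "--counts", str(sim / "counts"), "--adt", str(sim / "adt.csv"),
            "--model-out", str(root / "model.zip"),
            "--report-out", str(root / "report.json"),
            "--no-optimize", "--seed", "42",
        ]) == 0
        assert run([
            "predict", "--counts", str(sim / "counts"),
            "--model", str(root / "model.zip"), "--out", str(root / "pred.csv"),
        ]) == 0
        assert run([
            "evaluate", "--predictions", str(root / "pred.csv"),
            "--truth", str(sim / "truth.json"), "--out", str(root / "metrics.json"),
        ]) == 0
        return root, sim

    def test_end_to_end_outputs(self, pipeline_dir):
        root, sim = pipeline_dir
        pred = pd.read_csv(root / "pred.csv")
        truth = json.loads((sim / "truth.json").read_text())
        assert len(pred) == len(truth["is_positive"])  # one row per input cell
        assert set(pred.columns) == {"barcode", "label", "score"}
        metrics = json.loads((root / "metrics.json").read_text())
        assert metrics["accuracy"] > 0.9  # planted signal is easy

    def test_prediction_csv_deterministic(self, pipeline_dir, tmp_path):
        root, sim = pipeline_dir
        out2 = tmp_path / "pred2.csv"
        assert run([
            "predict", "--counts", str(sim / "counts"),
            "--model", str(root / "model.zip"), "--out", str(out2),
        ]) == 0
        assert out2.read_bytes() == (root / "pred.csv").read_bytes()

    def test_truncated_model_exits_2(self, pipeline_dir, tmp_path, capsys):
        root, sim = pipeline_dir
        bad = tmp_path / "bad.zip"
        data = (root / "model.zip").read_bytes()
        bad.write_bytes(data[: len(data) // 2])
        code = run([
            "predict", "--counts", str(sim / "counts"),
            "--model", str(bad), "--out", str(tmp_path / "p.csv"),
        ])
        assert code == 2
        assert "manifest hash mismatch" in capsys.readouterr().err

    def test_unknown_flag_exits_2(self):
        assert run(["predict", "--bogus"]) == 2

    def test_evaluate_perfect_predictions(self, tmp_path):
        pred = pd.DataFrame({
            "barcode": ["a", "b", "c", "d"],
            "label": ["positive", "negative", "positive", "negative"],
            "score": [0.9, 0.1, 0.8, 0.2],
        })
        pred.to_csv(tmp_path / "p.csv", index=False)
        truth = pd.DataFrame({"barcode": ["a", "b", "c", "d"],
                              "label": ["positive", "negative", "positive", "negative"]})
        truth.to_csv(tmp_path / "t.csv", index=False)
        assert run(["evaluate", "--predictions", str(tmp_path / "p.csv"),
                    "--truth", str(tmp_path / "t.csv"),
                    "--out", str(tmp_path / "m.json")]) == 0
        metrics = json.loads((tmp_path / "m.json").read_text())
        assert metrics["accuracy"] == 1.0
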