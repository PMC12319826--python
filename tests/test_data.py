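import numpy as np
import pytest

from soundbrain.data import (BoldMatrix, Manifest, RunRecord, SplitSpec,
                             extract_bold, load_audio, read_bold_tsv,
                             save_audio, split_runs, window_run,
                             window_samples, write_bold_tsv)


def make_manifest(n_runs: int, subject: str = "sub-01") -> Manifest:
    runs = []
    for i in range(n_runs):
        runs.append(RunRecord(subject=subject, season=1, episode=i // 2 + 1,
                              segment="ab"[i % 2], audio_path=f"r{i}.wav",
                              bold_path=f"r{i}.tsv", n_tr=100))
    return Manifest(runs)


class TestManifest:
    def test_duplicate_keys_rejected(self):
        r = RunRecord("sub-01", 1, 1, "a", "x.wav", "x.tsv", 10)
        with pytest.raises(ValueError, match="duplicate"):
            Manifest([r, r])

    def test_csv_round_trip(self, tmp_path):
        m = make_manifest(6)
        m.to_csv(tmp_path / "m.csv")
        back = Manifest.from_csv(tmp_path / "m.csv")
        assert [r.key for r in back] == [r.key for r in m]

    def test_n_tr_must_be_positive(self):
        with pytest.raises(ValueError):
            RunRecord("s", 1, 1, "a", "x", "y", 0)


class TestSplit:
    def test_canonical_146_run_split(self):
        tr, va = split_runs(make_manifest(146), SplitSpec(0.75, seed=0))
        assert (len(tr), len(va)) == (109, 37)

    def test_four_runs(self):
        tr, va = split_runs(make_manifest(4), SplitSpec(0.75, seed=1))
        assert (len(tr), len(va)) == (3, 1)

    def test_deterministic(self):
        m = make_manifest(20)
        a = split_runs(m, SplitSpec(0.75, seed=3))
        b = split_runs(m, SplitSpec(0.75, seed=3))
        assert [r.key for r in a[0]] == [r.key for r in b[0]]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_partition(self, seed):
        m = make_manifest(17)
        tr, va = split_runs(m, SplitSpec(0.6, seed=seed))
        keys_tr = {r.key for r in tr}
        keys_va = {r.key for r in va}
        assert not keys_tr & keys_va
        assert keys_tr | keys_va == {r.key for r in m}

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_runs(Manifest([]), SplitSpec())

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestAudio:
    def test_stereo_resample_to_mono(self, tmp_path):
        rng = np.random.default_rng(0)
        stereo = rng.uniform(-0.5, 0.5, (44100, 2)).astype(np.float32)
        import scipy.io.wavfile
        scipy.io.wavfile.write(tmp_path / "a.wav", 44100, stereo)
        wav = load_audio(tmp_path / "a.wav")
        assert wav.shape == (22050,)

    def test_native_rate_mono_passthrough(self, tmp_path):
        x = np.random.default_rng(1).uniform(-1, 1, 5000).astype(np.float32)
        save_audio(tmp_path / "b.wav", x)
        np.testing.assert_array_equal(load_audio(tmp_path / "b.wav"), x)

    def test_silence_in_silence_out(self, tmp_path):
        save_audio(tmp_path / "s.wav", np.zeros(3000, dtype=np.float32))
        assert not load_audio(tmp_path / "s.wav").any()

    def test_int16_scaled_to_unit(self, tmp_path):
        import scipy.io.wavfile
        x = (np.ones(1000) * 16384).astype(np.int16)
        scipy.io.wavfile.write(tmp_path / "i.wav", 22050, x)
        wav = load_audio(tmp_path / "i.wav")
        assert np.allclose(wav, 0.5, atol=1e-3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_audio(tmp_path / "nope.wav")


class TestBoldMatrix:
    def test_tsv_round_trip(self, tmp_path):
        bold = BoldMatrix(np.random.default_rng(2).standard_normal((7, 3)),
                          ["a", "b", "c"])
        write_bold_tsv(bold, tmp_path / "b.tsv")
        back = read_bold_tsv(tmp_path / "b.tsv")
        np.testing.assert_array_equal(back.values, bold.values)
        assert back.target_labels == bold.target_labels

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            BoldMatrix(np.array([[1.0, np.nan]]), ["a", "b"])


class TestWindowing:
    def test_window_samples_70_tr(self):
        assert window_samples(70) == 2_299_815

    def test_430_tr_run_at_w70(self):
        bold = BoldMatrix(np.arange(430 * 2, dtype=float).reshape(430, 2),
                          ["a", "b"])
        wav = np.zeros(window_samples(430), dtype=np.float32)
        windows = window_run(bold, wav, 70)
        assert len(windows) == 6  # 10-TR tail dropped
        assert all(a.size == window_samples(70) for a, _ in windows)
        # concatenated BOLD windows reproduce the source prefix
        cat = np.concatenate([b for _, b in windows])
        np.testing.assert_array_equal(cat, bold.values[:420])

    def test_w_equals_n_tr_gives_one_window(self):
        bold = BoldMatrix(np.zeros((30, 1)), ["a"])
        wav = np.zeros(window_samples(30), dtype=np.float32)
        assert len(window_run(bold, wav, 30)) == 1

    def test_w_exceeding_run_rejected(self):
        bold = BoldMatrix(np.zeros((10, 1)), ["a"])
        with pytest.raises(ValueError, match="exceeds"):
            window_run(bold, np.zeros(window_samples(10)), 11)

    def test_audio_shorter_than_bold_truncates(self):
        bold = BoldMatrix(np.zeros((40, 1)), ["a"])
        wav = np.zeros(window_samples(25), dtype=np.float32)
        assert len(window_run(bold, wav, 10)) == 2


class TestExtractBold:
    @staticmethod
    def _img(data):
        import nibabel as nib
        return nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))

    def test_parcel_means_hand_computed(self):
        atlas = np.zeros((2, 2, 1))
        atlas[0, 0, 0] = 1
        atlas[0, 1, 0] = 1
        atlas[1, 0, 0] = 2
        vol = np.zeros((2, 2, 1, 3))
        vol[0, 0, 0] = [1, 2, 3]
        vol[0, 1, 0] = [3, 4, 5]
        vol[1, 0, 0] = [10, 20, 30]
        bold = extract_bold(self._img(vol), self._img(atlas))
        np.testing.assert_allclose(bold.values[:, 0], [2, 3, 4])
        np.testing.assert_allclose(bold.values[:, 1], [10, 20, 30])

    def test_constant_volume_gives_constant_columns(self):
        atlas = np.ones((3, 3, 2))
        atlas[2, 2, 1] = 2
        vol = np.full((3, 3, 2, 4), 7.0)
        bold = extract_bold(self._img(vol), self._img(atlas), mode="labels")
        np.testing.assert_allclose(bold.values, 7.0)

    def test_binary_mask_gives_one_column_per_voxel(self):
        mask = np.zeros((2, 2, 2))
        mask[0, 0, 0] = 1
        mask[1, 1, 1] = 1
        vol = np.random.default_rng(3).standard_normal((2, 2, 2, 5))
        bold = extract_bold(self._img(vol), self._img(mask))
        assert bold.values.shape == (5, 2)

    def test_voxel_permutation_within_label_invariance(self):
        rng = np.random.default_rng(4)
        atlas = np.ones((4, 1, 1))
        vol = rng.standard_normal((4, 1, 1, 6))
        permuted = vol[[2, 0, 3, 1]]
        a = extract_bold(self._img(vol), self._img(atlas), mode="labels")
        b = extract_bold(self._img(permuted), self._img(atlas), mode="labels")
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_grid_mismatch_rejected(self):
        atlas = np.ones((2, 2, 2))
        vol = np.zeros((3, 3, 3, 2))
        with pytest.raises(ValueError, match="grid"):
            extract_bold(self._img(vol), self._img(atlas))
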