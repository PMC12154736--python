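"""mzML round trips, fragment matching, and DIA chromatogram extraction."""

import shutil
import subprocess

import numpy as np
import pytest

from ioncal import (
    FragmentPanel,
    MzmlError,
    TransitionTarget,
    extract_dia_chromatograms,
    extract_fragment_intensities,
    read_ms2_spectra,
    read_panel_csv,
    read_transition_csv,
    write_mzml,
)
from ioncal.msio import SpectrumRecord

from conftest import make_spectrum


class TestSpectrumRecord:
    def test_rejects_mismatched_arrays(self):
        with pytest.raises(ValueError, match="length"):
            make_spectrum(mz=(1.0, 2.0), intensity=(1.0,))

    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="ascending"):
            make_spectrum(mz=(2.0, 1.0, 3.0))

    def test_rejects_nonpositive_injection_time(self):
        with pytest.raises(ValueError, match="injection time"):
            make_spectrum(injection_time=0.0)

    def test_tic_recomputed_from_intensities(self):
        s = make_spectrum(intensity=(1.0, 2.0, 3.5))
        assert s.tic == pytest.approx(6.5, rel=1e-6)

    def test_window_membership_half_open(self):
        s = make_spectrum(iso_center=500.0, iso_width=2.0)
        assert s.window_contains(499.0)
        assert s.window_contains(500.999999)
        assert not s.window_contains(501.0)  # upper edge belongs to next window
        assert not s.window_contains(498.999)


class TestMzmlRoundTrip:
    def test_write_then_read_identity(self, infusion_run, tmp_path):
        """m/z, intensity, injection time and RT survive a write/read cycle."""
        _, spectra, _ = infusion_run
        path = tmp_path / "run.mzML"
        write_mzml(spectra[:50], path)
        back = read_ms2_spectra(path)
        assert len(back) == 50
        for orig, rec in zip(spectra[:50], back):
            np.testing.assert_allclose(rec.mz_values, orig.mz_values, rtol=1e-6)
            np.testing.assert_array_equal(rec.intensities, orig.intensities)
            assert rec.injection_time == pytest.approx(orig.injection_time, rel=1e-6)
            assert rec.retention_time == pytest.approx(orig.retention_time, rel=1e-6)
            assert rec.isolation_center == pytest.approx(orig.isolation_center)

    def test_empty_rt_interval_gives_empty_list(self, infusion_run, tmp_path):
        _, spectra, _ = infusion_run
        path = tmp_path / "run.mzML"
        write_mzml(spectra[:5], path)
        assert read_ms2_spectra(path, rt_range=(0.0, 0.0)) == []

    def test_rt_filter_half_open(self, tmp_path):
        spectra = [make_spectrum(scan_index=i, rt=float(i)) for i in range(5)]
        path = tmp_path / "run.mzML"
        write_mzml(spectra, path)
        kept = read_ms2_spectra(path, rt_range=(1.0, 3.0))
        assert [s.retention_time for s in kept] == [1.0, 2.0]

    def test_missing_injection_time_rejected(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml([make_spectrum()], path)
        text = path.read_text().replace("ion injection time", "some other time")
        bad = tmp_path / "bad.mzML"
        bad.write_text(text.replace("MS:1000927", "MS:9999999"))
        with pytest.raises(MzmlError, match="injection time"):
            read_ms2_spectra(bad)

    def test_profile_spectrum_rejected(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml([make_spectrum()], path)
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        bad = tmp_path / "profile.mzML"
        bad.write_text(text)
        with pytest.raises(MzmlError, match="centroid"):
            read_ms2_spectra(bad)

    def test_malformed_mzml_raises_parse_error(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml([make_spectrum()], path)
        (tmp_path / "trunc.mzML").write_text(path.read_text()[:-200])
        with pytest.raises(MzmlError, match="malformed"):
            read_ms2_spectra(tmp_path / "trunc.mzML")

    def test_deterministic_output_bytes(self, infusion_run, tmp_path):
        _, spectra, _ = infusion_run
        write_mzml(spectra[:10], tmp_path / "a.mzML")
        write_mzml(spectra[:10], tmp_path / "b.mzML")
        assert (tmp_path / "a.mzML").read_bytes() == (tmp_path / "b.mzML").read_bytes()

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_round_trip_agrees_with_mzr(self, infusion_run, tmp_path):
        """Independent oracle: Bioconductor mzR reads our mzML identically."""
        _, spectra, _ = infusion_run
        path = tmp_path / "run.mzML"
        write_mzml(spectra[:20], path)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(mzR))\n"
            "h <- openMSfile(commandArgs(TRUE)[1])\n"
            "hd <- header(h)\n"
            "p <- peaks(h, 2)\n"
            "cat(nrow(hd), hd$injectionTime[1], hd$retentionTime[3],"
            " nrow(p), sprintf('%.6f', sum(p[,2])), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script), str(path)],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        assert int(out[0]) == 20
        assert float(out[1]) == pytest.approx(spectra[0].injection_time, rel=1e-6)
        assert float(out[2]) == pytest.approx(spectra[2].retention_time * 60, rel=1e-6)
        assert int(out[3]) == spectra[1].mz_values.size
        assert float(out[4]) == pytest.approx(spectra[1].intensities.sum(), rel=1e-9)


class TestFragmentPanel:
    def test_reference_must_be_member(self):
        with pytest.raises(ValueError, match="reference"):
            FragmentPanel(target_mzs=(100.0, 200.0), reference_mz=300.0, tolerance=10)

    def test_ambiguous_targets_rejected(self):
        # 500.000 and 500.005 are within 2x the 10 ppm tolerance (~0.01 Th)
        with pytest.raises(ValueError, match="ambiguous"):
            FragmentPanel(target_mzs=(500.0, 500.005), reference_mz=500.0, tolerance=10)

    def test_panel_csv_round_trip(self, tmp_path):
        p = tmp_path / "panel.csv"
        p.write_text(
            "target_mz,is_reference,tolerance,tolerance_unit\n"
            "480.23,False,10,ppm\n942.43,True,10,ppm\n"
        )
        panel = read_panel_csv(p)
        assert panel.reference_mz == 942.43
        assert panel.target_mzs == (480.23, 942.43)

    def test_panel_csv_requires_single_reference(self, tmp_path):
        p = tmp_path / "panel.csv"
        p.write_text(
            "target_mz,is_reference,tolerance,tolerance_unit\n"
            "480.23,True,10,ppm\n942.43,True,10,ppm\n"
        )
        with pytest.raises(ValueError, match="exactly one reference"):
            read_panel_csv(p)


class TestExtractFragmentIntensities:
    def test_exact_match(self):
        panel = FragmentPanel(target_mzs=(200.0, 500.0), reference_mz=500.0, tolerance=10)
        s = make_spectrum(mz=(500.0,), intensity=(500.0,))
        mat = extract_fragment_intensities([s], panel)
        assert mat.column(500.0)[0] == 500.0
        assert mat.column(200.0)[0] == 0.0

    def test_most_intense_centroid_wins(self):
        panel = FragmentPanel(target_mzs=(200.0, 500.0), reference_mz=500.0,
                              tolerance=0.01, tolerance_unit="mz")
        s = make_spectrum(mz=(499.995, 500.004), intensity=(300.0, 700.0))
        mat = extract_fragment_intensities([s], panel)
        assert mat.column(500.0)[0] == 700.0

    def test_jittered_simulator_output_recovered_exactly(self, infusion_run, glufib_panel):
        """5 ppm m/z jitter within a 10 ppm window: extraction reproduces the
        simulator's emission log cell for cell."""
        config, _, _ = infusion_run
        from ioncal import SyntheticInfusionConfig, simulate_infusion

        jcfg = SyntheticInfusionConfig(
            n_spectra=200,
            fragment_mzs=config.fragment_mzs,
            mean_ions_per_fill=config.mean_ions_per_fill,
            injection_time=config.injection_time,
            mz_jitter_ppm=5.0,
            seed=21,
        )
        spectra, ledger = simulate_infusion(jcfg)
        mat = extract_fragment_intensities(spectra, glufib_panel)
        for mz in jcfg.fragment_mzs:
            truth = ledger[ledger.fragment_mz == mz].sort_values("scan_index")
            np.testing.assert_array_equal(mat.column(mz), truth.intensity.to_numpy())

    def test_permutation_equivariance(self, infusion_run, glufib_panel):
        _, spectra, _ = infusion_run
        sub = spectra[:40]
        mat = extract_fragment_intensities(sub, glufib_panel)
        perm = np.arange(len(sub))[::-1]
        mat_perm = extract_fragment_intensities([sub[i] for i in perm], glufib_panel)
        np.testing.assert_array_equal(mat_perm.values, mat.values[perm])


class TestDiaChromatograms:
    def _spec(self, rt, center, frags, intens):
        return make_spectrum(rt=rt, iso_center=center, iso_width=2.0,
                             mz=frags, intensity=intens)

    def test_transition_sum_additivity(self):
        s = self._spec(1.0, 500.0, (300.0, 400.0), (100.0, 200.0))
        target = TransitionTarget("a", 500.5, (300.0, 400.0, 700.0),
                                  boundary_start=0.0, boundary_end=2.0)
        chrom = extract_dia_chromatograms([s], [target])["a"]
        assert len(chrom) == 1
        assert chrom.intensities[0] == 300.0  # 100 + 200 + 0 for the unmatched

    def test_joint_equals_sum_of_single_fragment_extractions(self):
        s = self._spec(1.0, 500.0, (300.0, 400.0, 450.0), (10.0, 20.0, 40.0))
        frags = (300.0, 400.0, 450.0)
        joint = extract_dia_chromatograms(
            [s], [TransitionTarget("j", 500.0, frags)])["j"]
        singles = [
            extract_dia_chromatograms(
                [s], [TransitionTarget(f"s{f}", 500.0, (f,))])[f"s{f}"]
            for f in frags
        ]
        assert joint.intensities[0] == sum(c.intensities[0] for c in singles)

    def test_precursor_on_upper_edge_goes_to_next_window(self):
        lower = self._spec(1.0, 500.0, (300.0,), (1.0,))
        upper = self._spec(1.1, 502.0, (300.0,), (2.0,))
        target = TransitionTarget("edge", 501.0, (300.0,))
        chrom = extract_dia_chromatograms([lower, upper], [target])["edge"]
        assert len(chrom) == 1
        assert chrom.intensities[0] == 2.0

    def test_unmatched_target_warns_with_empty_chromatogram(self):
        s = self._spec(1.0, 500.0, (300.0,), (1.0,))
        target = TransitionTarget("ghost", 800.0, (300.0,))
        with pytest.warns(UserWarning, match="ghost"):
            chrom = extract_dia_chromatograms([s], [target])["ghost"]
        assert len(chrom) == 0

    def test_simulated_peak_matches_ledger_per_scan(self, dia_run):
        _, spectra, ledger, target = dia_run
        chrom = extract_dia_chromatograms(spectra, [target])["PEP1"]
        truth = ledger.per_scan.sort_values("scan_index")
        np.testing.assert_allclose(chrom.intensities, truth.intensity.to_numpy(),
                                   rtol=1e-12)
        np.testing.assert_allclose(chrom.retention_times, truth.rt_min.to_numpy(),
                                   rtol=1e-12)


class TestTransitionCsv:
    def test_groups_rows_by_analyte(self, tmp_path):
        p = tmp_path / "transitions.csv"
        p.write_text(
            "analyte_id,precursor_mz,fragment_mz,boundary_start_min,boundary_end_min\n"
            "a,500.5,300.0,1.0,2.0\na,500.5,400.0,1.0,2.0\nb,600.5,350.0,3.0,4.0\n"
        )
        targets = read_transition_csv(p)
        assert [t.analyte_id for t in targets] == ["a", "b"]
        assert targets[0].fragment_mzs == (300.0, 400.0)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "transitions.csv"
        p.write_text("analyte_id,precursor_mz\n" "a,500.5\n")
        with pytest.raises(ValueError, match="fragment_mz"):
            read_transition_csv(p)
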