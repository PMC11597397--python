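"""Domain types, the bundled narwhal dataset, and CSV round-tripping."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

import bombpulse as bp
from bombpulse.core import SAMPLE_COLUMNS

HEADER = ",".join(SAMPLE_COLUMNS)


class TestBundledDataset:
    def test_counts(self, narwhal):
        assert len(narwhal) == 11
        assert narwhal.n_samples == 46
        assert sum(1 for s in narwhal.samples() if s.has_isotopes) == 36

    @pytest.mark.parametrize(
        "sid, layer, year, pmc, pmc_sd",
        [
            ("956", 1, 1958, 94.87, 0.26),
            ("4076", 54, 2003, 103.15, 0.34),
            ("562", 0, 1892, 93.27, 0.35),  # embedded-tooth prenatal tip
            ("1336", 0, 1938, 92.65, 0.39),
            ("1269", 10, 1968, 101.28, 0.36),
        ],
    )
    def test_transcribed_rows(self, narwhal, sid, layer, year, pmc, pmc_sd):
        s = narwhal.get(sid).sample_at(layer)
        assert s.year == year
        assert s.pmc == pytest.approx(pmc)
        assert s.pmc_sd == pytest.approx(pmc_sd)

    def test_repeat_measurements_of_one_layer_all_kept(self, narwhal):
        # tusk no. 4076 GLG 11 was measured three times (twice at one lab)
        reps = [s for s in narwhal.get("4076").samples if s.layer_index == 11]
        assert sorted(s.pmc for s in reps) == [98.28, 99.03, 99.55]

    def test_metadata_attached(self, narwhal):
        sp = narwhal.get("956")
        assert sp.specimen_type == bp.SpecimenType.TUSK
        assert sp.layers_missing == (1, 3)
        assert sp.year_of_death == 2010
        assert narwhal.get("4076").layers_missing == (10, 10)
        assert narwhal.get("1269").neonatal_line == bp.NeonatalLine.PRESENT

    def test_lab_split_matches_sample_counts(self, narwhal):
        aarhus = [s for s in narwhal.samples() if (s.lab_id or "").startswith("AAR")]
        assert len(aarhus) == 36
        assert sum(1 for s in narwhal.samples() if s.lab_id is None) == 10


class TestReadWrite:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(HEADER + "\n")
        assert len(bp.read_samples(p)) == 0

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "\nx1,narwhal,M,tusk,2000,1,1960,abc,0.3,,,,,\n")
        with pytest.raises(bp.ParseError, match=r"row 2.*'pmc'"):
            bp.read_samples(p)

    def test_exact_duplicate_row_rejected(self, tmp_path):
        row = "x1,narwhal,M,tusk,2000,1,1960,98.0,0.3,,,,,LAB"
        p = tmp_path / "dup.csv"
        p.write_text(HEADER + f"\n{row}\n{row}\n")
        with pytest.raises(bp.ParseError, match="duplicate"):
            bp.read_samples(p)

    def test_bundled_roundtrip(self, narwhal, tmp_path):
        p, m = tmp_path / "s.csv", tmp_path / "m.csv"
        bp.write_samples(narwhal, p, meta_path=m)
        back = bp.read_samples(p, meta_path=m)
        assert back.specimens == narwhal.specimens

    def test_missing_isotopes_roundtrip_as_empty_cells(self, narwhal, tmp_path):
        p = tmp_path / "s.csv"
        bp.write_samples(narwhal, p)
        text = p.read_text()
        assert ",,,," in text  # no. 953 rows carry no isotopes
        back = bp.read_samples(p)
        assert back.get("953").sample_at(1).d13c is None


def _sample_strategy(sid):
    opt = st.none() | st.floats(-30, 30).map(lambda v: round(v, 2))
    return st.builds(
        bp.RadiocarbonSample,
        specimen_id=st.just(sid),
        species=st.sampled_from(bp.Species),
        layer_index=st.integers(0, 60),
        year=st.none() | st.integers(1800, 2100).map(float),
        pmc=st.floats(50, 150).map(lambda v: round(v, 2) or 50.0),
        pmc_sd=st.floats(0.01, 2).map(lambda v: round(v, 2) or 0.01),
        d13c=opt,
        d15n=opt,
        lab_id=st.none() | st.text("ABC-123", min_size=1, max_size=8),
    )


def _specimen_strategy(sid):
    return st.builds(
        bp.Specimen,
        specimen_id=st.just(sid),
        species=st.sampled_from(bp.Species),
        sex=st.sampled_from(bp.Sex),
        specimen_type=st.sampled_from(bp.SpecimenType),
        year_of_death=st.none() | st.integers(1900, 2030).map(float),
        layers_counted=st.none() | st.integers(1, 80),
        layers_missing=st.tuples(st.integers(0, 3), st.integers(0, 10)).map(
            lambda t: (min(t), max(t))
        ),
        neonatal_line=st.sampled_from(bp.NeonatalLine),
        samples=st.lists(_sample_strategy(sid), min_size=1, max_size=4).map(tuple),
    )


datasets = st.integers(1, 3).flatmap(
    lambda n: st.tuples(*[_specimen_strategy(f"sp{i}") for i in range(n)])
).map(lambda sps: bp.Dataset(specimens=sps))


@given(ds=datasets)
def test_roundtrip_identity_property(ds, tmp_path_factory):
    """write_samples then read_samples reproduces any valid dataset exactly."""
    d = tmp_path_factory.mktemp("rt")
    p, m = d / "s.csv", d / "m.csv"
    # de-duplicate rows that the reader would (rightly) reject as double entry
    seen, ok = set(), True
    for s in ds.samples():
        key = (s.specimen_id, s.layer_index, s.lab_id, s.pmc)
        if key in seen:
            ok = False
        seen.add(key)
    if not ok:
        return
    bp.write_samples(ds, p, meta_path=m)
    back = bp.read_samples(p, meta_path=m)
    assert back.specimens == ds.specimens


def test_invariants_rejected():
    with pytest.raises(ValueError):
        bp.RadiocarbonSample("x", bp.Species.NARWHAL, 1, 1960.0, -5.0, 0.3)
    with pytest.raises(ValueError):
        bp.RadiocarbonSample("x", bp.Species.NARWHAL, -1, 1960.0, 95.0, 0.3)
    with pytest.raises(ValueError):
        bp.RadiocarbonSample("x", bp.Species.NARWHAL, 1, 1750.0, 95.0, 0.3)
    with pytest.raises(ValueError, match="duplicate specimen ids"):
        sp = bp.Specimen(specimen_id="a", species=bp.Species.NARWHAL)
        bp.Dataset(specimens=(sp, sp))
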