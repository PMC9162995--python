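import pytest

import fragility as fr


@pytest.fixture
def fast_config():
    """Analysis settings with a reduced bootstrap for quick tests."""
    return fr.RunConfig(n_boot=200, seed=2014)


@pytest.fixture
def mixed_records():
    """Two significant and two nonsignificant comparisons."""
    return [
        fr.ComparisonRecord("study-1", "mortality", "primary",
                            fr.FourfoldTable(0, 5, 5, 5)),
        fr.ComparisonRecord("study-1", "wound infection", "secondary",
                            fr.FourfoldTable(1, 100, 9, 100)),
        fr.ComparisonRecord("study-2", "reoperation", "other",
                            fr.FourfoldTable(3, 10, 3, 10)),
        fr.ComparisonRecord("study-3", "readmission", "primary",
                            fr.FourfoldTable(2, 5, 5, 5)),
    ]


@pytest.fixture
def corpus_csv(tmp_path, mixed_records):
    path = tmp_path / "corpus.csv"
    fr.write_corpus(path, mixed_records)
    return path
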