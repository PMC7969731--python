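import numpy as np
import pytest

from awakerest import decoder as dec
from awakerest import preprocess as pp
from awakerest import synthetic as syn


@pytest.fixture(scope="session")
def design():
    return syn.DecoderScanDesign()


@pytest.fixture(scope="session")
def tuning():
    # a V1-sized ROI: 24 voxels, half orientation-selective
    return syn.make_tuning(24, 12, 0.25, seed=11)


@pytest.fixture(scope="session")
def decoder_dataset(design, tuning):
    """Simulated decoder-construction scan, preprocessed into samples."""
    runs, labels = syn.generate_decoder_scan(design, tuning, seed=21)
    samples, mask = pp.preprocess_decoder_runs(runs, labels, design)
    return {"runs": runs, "labels": labels, "samples": samples, "mask": mask}


@pytest.fixture(scope="session")
def fitted_model(decoder_dataset):
    return dec.fit(decoder_dataset["samples"])


@pytest.fixture(scope="session")
def rest_windows(decoder_dataset, tuning):
    """Null (no planted signal) rest windows preprocessed with the mask."""
    rd = syn.RestScanDesign(planted_amplitude=0.0)
    scan = syn.generate_rest_scan(rd, tuning, seed=31)
    return pp.preprocess_rest_scan(scan, decoder_dataset["mask"])
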