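import numpy as np
import pytest

from pdscreen import pipeline, synthetic, tables


@pytest.fixture(scope="session")
def tiny_config() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(
        n_pd=6, n_hc=5, seed=11, task_codes=("TSK3", "TSK18"),
        vowel_s=1.2, ddk_s=2.0, speech_s=5.0, video_s=4.0)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return synthetic.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_tables(tiny_bundle):
    """Assembled + residualized per-modality tables of the tiny cohort."""
    video = pipeline.extract_video_features(tiny_bundle.landmarks)
    audio = pipeline.extract_audio_features(tiny_bundle.audio)
    audio = audio.dropna(axis=1, how="all")
    out = {}
    for mod in ("video", "audio", "multimodal"):
        t = tables.assemble_table(video, audio, tiny_bundle.metadata, mod)
        out[mod] = tables.regress_out(t)
    out["video_raw"] = video
    out["audio_raw"] = audio
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
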