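import numpy as np
import pandas as pd
import pytest

import siamscore as ss


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small generated cohort shared by read-only tests."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    config = ss.rop_config(n_patients=12, seed=7)
    ss.generate_cohort(config, out)
    return {"dir": out, "config": config,
            "manifest": ss.load_manifest(out / "manifest.csv")}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def linear_model():
    """Frozen affine embedding on 8x8 images; every downstream quantity has
    a closed form under it."""
    gen = np.random.default_rng(3)
    matrix = gen.normal(size=(4, 64))
    return ss.LinearEmbedder(matrix, input_size=(8, 8))


def constant_image_manifest(tmp_path, values, grades, unit="U0", patient="P0"):
    """Write constant-intensity PNGs; severity is encoded in the pixel value,
    so a LinearEmbedder over the pixel sum recovers it exactly."""
    from PIL import Image

    tmp_path.mkdir(parents=True, exist_ok=True)
    rows = []
    for t, (v, g) in enumerate(zip(values, grades)):
        arr = np.full((8, 8), int(round(v * 255)), dtype=np.uint8)
        path = tmp_path / f"{unit}_T{t}.png"
        Image.fromarray(arr, mode="L").save(path)
        rows.append({"patient_id": patient, "unit_id": unit, "timepoint": t,
                     "latent_severity": v, "grade": g, "image_path": str(path),
                     "split": "test"})
    return pd.DataFrame(rows)
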