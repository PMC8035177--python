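import numpy as np
import pytest

import spikecoder as sc

#: the experimental stimulus grid: 0-5 V in 0.5 V steps
LEVELS = np.round(np.arange(0, 10.5) * 0.5, 1)

#: thresholding current of the reference rate-encoding protocol
IST = 5e-10


@pytest.fixture(scope="session")
def device():
    return sc.default_calibration()


@pytest.fixture(scope="session")
def quiet_device(device):
    """Default calibration with readout noise disabled (closed-form oracles)."""
    return sc.noise_free(device)


@pytest.fixture(scope="session")
def mnist_device():
    return sc.mnist_calibration()


@pytest.fixture(scope="session")
def gradient64():
    return sc.make_fixture(sc.Fixture(kind="gradient", shape=(64, 64)))


@pytest.fixture(scope="session")
def blob_data():
    """10-class blob digits: 1000 train + 500 test images, 28x28."""
    images, labels = sc.make_fixture(
        sc.Fixture(kind="blob-digits", shape=(28, 28), n_classes=10, n_images=1500, seed=4)
    )
    return (images[:1000], labels[:1000]), (images[1000:], labels[1000:])


@pytest.fixture(scope="session")
def trained_model(blob_data):
    """ANN trained on the blob fixture at the reference protocol (lr 1e-4, 100 epochs)."""
    (xtr, ytr), _ = blob_data
    return sc.train_ann(xtr, ytr, lr=1e-4, epochs=100, seed=0)


@pytest.fixture(scope="session")
def balanced_model(trained_model, blob_data, mnist_device):
    (xtr, _), _ = blob_data
    prog = sc.rate_program(mu_tg=-5.5, sigma_tg=1.0, seed=0)
    calib = np.stack(
        [
            sc.encoder_frontend(im, prog, mnist_device, 2e-10, 100, seed=1000 + i)
            for i, im in enumerate(xtr[:100])
        ]
    )
    sc.threshold_balance(trained_model, calib)
    return trained_model
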