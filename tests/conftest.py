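import numpy as np
import pytest

import her2quant as hq


@pytest.fixture(scope="session")
def vectors():
    return hq.StainVectors.hdab()


@pytest.fixture(scope="session")
def stained_patch():
    """50 well-separated cells, 30% positive with complete membranes."""
    img, truth = hq.make_patch(
        50, positive_fraction=0.3, completeness=1.0, dab_od=0.8, rng_seed=1
    )
    return img, truth


@pytest.fixture(scope="session")
def classifier_fixture():
    """2,000 tiles: tumor = DAB-bearing cell-dense, non-tumor = sparse unstained.

    Separable by construction; 128 px tiles keep the fixture fast while
    preserving the density contrast.
    """
    rng = np.random.default_rng(42)
    patches, labels = [], []
    for i in range(2000):
        tumor = i % 2 == 0
        seed = int(rng.integers(0, 2**31 - 1))
        if tumor:
            img, _ = hq.make_patch(
                14, positive_fraction=0.3, dab_od=0.6, rng_seed=seed, size=128
            )
        else:
            img, _ = hq.make_patch(
                2, positive_fraction=0.0, dab_od=0.0, rng_seed=seed, size=128
            )
        patches.append(img.pixels)
        labels.append(int(tumor))
    return patches, np.array(labels)


@pytest.fixture(scope="session")
def slide_2plus():
    return hq.make_slide("2+", n_tiles=2, rng_seed=5)


@pytest.fixture(scope="session")
def slide_0():
    return hq.make_slide("0", n_tiles=2, rng_seed=5)


def otsu_bruteforce(hist) -> int:
    """Independent oracle: exhaustive scan of all candidate thresholds."""
    hist = [float(h) for h in hist]
    total = sum(hist)
    msum = sum(i * h for i, h in enumerate(hist))
    best_t, best_v = 0, -1.0
    w0 = m0 = 0.0
    for t in range(255):
        w0 += hist[t]
        m0 += t * hist[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0, mu1 = m0 / w0, (msum - m0) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def stained_pixel_mask(truth, shape):
    """Ground-truth DAB pixel mask rebuilt from the cell specs."""
    from her2quant.synthetic import _arc_pixels

    mask = np.zeros(shape, bool)
    for cell in truth.cells:
        if cell.dab_od > 0 and cell.membrane_completeness > 0:
            rr, cc = _arc_pixels(cell, shape)
            mask[rr, cc] = True
    return mask
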