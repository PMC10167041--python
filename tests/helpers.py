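"""Shared generators for test inputs."""

import numpy as np
from scipy import ndimage


def random_blob_mask(rng, shape, occupancy=0.45, smooth=1.5):
    """Random smooth binary mask with blobby structure."""
    field = ndimage.gaussian_filter(rng.normal(size=shape), smooth)
    return field > np.quantile(field, 1.0 - occupancy)


def random_histogram(rng, n_occupied=None):
    """Random sparse 8-bit gray histogram."""
    hist = np.zeros(256)
    k = int(n_occupied if n_occupied is not None else rng.integers(4, 48))
    bins = rng.choice(256, size=k, replace=False)
    hist[bins] = rng.integers(1, 2000, size=k)
    return hist


def digital_ball(radius, pad=1):
    """Digital ball: voxel centers within `radius` of the central voxel."""
    n = int(np.ceil(radius)) + pad
    zz, yy, xx = np.ogrid[-n:n + 1, -n:n + 1, -n:n + 1]
    return (zz * zz + yy * yy + xx * xx) <= radius * radius
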