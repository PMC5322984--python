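"""k-space formation, noise, and Cartesian reconstruction.

k-space indexing puts DC at the grid center (fftshift convention):
encode = fftshift(fft(ifftshift(image))) and recon is its exact
inverse, so encode->recon round-trips to machine precision and
Parseval holds with the 1/N normalization of the inverse DFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KSpaceData",
    "accumulate_kspace",
    "encode_dft",
    "add_noise",
    "recon_cartesian",
]


@dataclass
class KSpaceData:
    """Complex Cartesian samples + acquisition metadata."""

    samples: np.ndarray
    metadata: dict = field(default_factory=dict)
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)


def accumulate_kspace(adc_records, encoding, receive_maps=None,
                      metadata=None) -> KSpaceData:
    """Sum per-voxel signals into k-space samples.

    ``adc_records``: array (n_voxels, n_samples) of complex per-voxel
    signals, one column per k-space sample; ``encoding``: array
    (n_samples, ...) of flat k-grid indices or an output grid shape
    tuple when samples are already ordered; ``receive_maps``: optional
    (n_voxels,) or (n_voxels, n_channels) complex sensitivities.
    Linear in each voxel's magnetization.
    """
    rec = np.asarray(adc_records, dtype=complex)
    if rec.ndim != 2:
        raise ValueError("adc_records must be (n_voxels, n_samples)")
    nv, ns = rec.shape
    if receive_maps is None:
        sens = np.ones(nv)
    else:
        sens = np.asarray(receive_maps, dtype=complex)
        if sens.shape[0] != nv:
            raise ValueError("receive map / record mismatch")
    if sens.ndim == 1:
        combined = sens @ rec  # (n_samples,)
    else:
        combined = np.einsum("vc,vs->cs", sens.conj(), rec)
    if isinstance(encoding, tuple):
        shape = encoding
        if int(np.prod(shape)) != ns:
            raise ValueError("encoding shape does not match sample count")
        samples = combined.reshape((-1,) + shape if sens.ndim > 1 else shape)
    else:
        idx = np.asarray(encoding)
        if idx.shape[0] != ns:
            raise ValueError("encoding table / record mismatch")
        flat = np.zeros(int(idx.max()) + 1, dtype=complex)
        np.add.at(flat, idx, combined if sens.ndim == 1 else combined[0])
        samples = flat
    return KSpaceData(samples, dict(metadata or {}))


def _axes(img_ndim, shape_len):
    return tuple(range(img_ndim - shape_len, img_ndim))


def encode_dft(signal_map: np.ndarray) -> KSpaceData:
    """Ideal Cartesian encoding of a per-voxel complex signal map:
    sample(k) = sum_r m(r) exp(-2*pi*i k.r/N), DC at grid center."""
    m = np.asarray(signal_map, dtype=complex)
    k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(m)))
    return KSpaceData(k, {"matrix": m.shape})


def add_noise(k: KSpaceData, sigma: float, seed: int = 0,
              relative_to_dc: bool = False) -> KSpaceData:
    """Add i.i.d. complex Gaussian noise (std ``sigma`` per component).

    With ``relative_to_dc`` the level is a fraction of the magnitude of
    the largest (DC) sample of the noiseless data.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = sigma * np.abs(k.samples).max() if relative_to_dc else sigma
    if s == 0:
        return KSpaceData(k.samples.copy(), dict(k.metadata), noise_sigma=0.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, s, k.samples.shape) \
        + 1j * rng.normal(0.0, s, k.samples.shape)
    return KSpaceData(k.samples + noise, dict(k.metadata), noise_sigma=s)


def recon_cartesian(k: KSpaceData) -> np.ndarray:
    """Centered inverse DFT of a fully sampled Cartesian grid."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k.samples)))


def save_hdf5(k: KSpaceData, path, name: str = "kspace") -> None:
    import h5py
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=k.samples)
        d.attrs["noise_sigma"] = k.noise_sigma
        for key, val in k.metadata.items():
            try:
                d.attrs[key] = val
            except TypeError:
                d.attrs[key] = str(val)


def load_hdf5(path, name: str = "kspace") -> KSpaceData:
    import h5py
    with h5py.File(path, "r") as f:
        d = f[name]
        meta = {k: v for k, v in d.attrs.items() if k != "noise_sigma"}
        return KSpaceData(d[...], meta, float(d.attrs.get("noise_sigma", 0.0)))


def magnitude_to_nifti(image: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)):
    import nibabel as nib
    arr = np.abs(image).astype(np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
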