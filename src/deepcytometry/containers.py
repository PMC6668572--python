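"""HDF5 containers for waveform cohorts and prepared datasets, plus
checkpoint archives for trained networks.  Round trips are bit-exact."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .network import ModelConfig, Network, build_network
from .prep import DatasetSplits
from .simulate import CellSpec, RawWaveform

__all__ = [
    "FormatError",
    "save_waveforms",
    "load_waveforms",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


class FormatError(ValueError):
    """A container file is missing a required group, dataset or attribute."""


_ANNOTATION_DTYPE = np.dtype([
    ("label", "S16"),
    ("center_sample", "i8"),
    ("center_position_um", "f8"),
    ("diameter_um", "f8"),
    ("contrast", "f8"),
    ("texture_scale_um", "f8"),
])


def save_waveforms(path, waveforms) -> None:
    """Write a cohort to ``/waveforms/<id>/samples`` (+ annotations table)."""
    with h5py.File(path, "w") as f:
        root = f.create_group("waveforms")
        for wf in waveforms:
            g = root.create_group(wf.waveform_id or f"wf{len(root):04d}")
            g.create_dataset("samples", data=wf.samples.astype(np.float32))
            g.attrs["sampling_rate"] = wf.sampling_rate
            g.attrs["repetition_rate"] = wf.repetition_rate
            g.attrs["pulse_period_samples"] = wf.pulse_period_samples
            g.attrs["start_phase_samples"] = wf.start_phase_samples
            ann = np.zeros(len(wf.annotations), dtype=_ANNOTATION_DTYPE)
            for i, (cell, center) in enumerate(wf.annotations):
                ann[i] = (cell.label.encode(), center, cell.center_position_um,
                          cell.diameter_um, cell.amplitude_contrast,
                          cell.texture_scale_um)
            g.create_dataset("annotations", data=ann)


def load_waveforms(path) -> list[RawWaveform]:
    waveforms = []
    with h5py.File(path, "r") as f:
        if "waveforms" not in f:
            raise FormatError(f"{path}: missing group 'waveforms'")
        for wid in sorted(f["waveforms"]):
            g = f["waveforms"][wid]
            for required in ("samples", "annotations"):
                if required not in g:
                    raise FormatError(
                        f"{path}: waveform {wid!r} missing dataset "
                        f"{required!r}")
            for attr in ("sampling_rate", "repetition_rate",
                         "pulse_period_samples", "start_phase_samples"):
                if attr not in g.attrs:
                    raise FormatError(
                        f"{path}: waveform {wid!r} missing attribute {attr!r}")
            annotations = []
            for row in g["annotations"][()]:
                cell = CellSpec(
                    label=row["label"].decode(),
                    center_position_um=float(row["center_position_um"]),
                    diameter_um=float(row["diameter_um"]),
                    amplitude_contrast=float(row["contrast"]),
                    texture_scale_um=float(row["texture_scale_um"]),
                )
                annotations.append((cell, int(row["center_sample"])))
            waveforms.append(RawWaveform(
                samples=g["samples"][()],
                pulse_period_samples=int(g.attrs["pulse_period_samples"]),
                start_phase_samples=int(g.attrs["start_phase_samples"]),
                sampling_rate=float(g.attrs["sampling_rate"]),
                repetition_rate=float(g.attrs["repetition_rate"]),
                annotations=annotations,
                waveform_id=wid,
            ))
    return waveforms


def save_dataset(path, X, y, splits: DatasetSplits, meta: dict | None = None) -> None:
    """Write a prepared dataset: X, y, split index vectors, JSON sidecar
    metadata as a root attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=np.asarray(X, dtype=np.float32))
        f.create_dataset("y", data=np.asarray(y, dtype=np.uint8))
        g = f.create_group("splits")
        g.create_dataset("train", data=splits.train)
        g.create_dataset("validation", data=splits.validation)
        g.create_dataset("test", data=splits.test)
        g.attrs["fractions"] = list(splits.fractions)
        g.attrs["split_seed"] = splits.split_seed
        f.attrs["meta"] = json.dumps(meta or {})


def load_dataset(path):
    with h5py.File(path, "r") as f:
        for required in ("X", "y", "splits"):
            if required not in f:
                raise FormatError(f"{path}: missing group/dataset {required!r}")
        for sub in ("train", "validation", "test"):
            if sub not in f["splits"]:
                raise FormatError(f"{path}: missing split index {sub!r}")
        X = f["X"][()]
        y = f["y"][()]
        splits = DatasetSplits(
            train=f["splits"]["train"][()],
            validation=f["splits"]["validation"][()],
            test=f["splits"]["test"][()],
            fractions=tuple(f["splits"].attrs.get("fractions", (0.8, 0.1, 0.1))),
            split_seed=int(f["splits"].attrs.get("split_seed", 0)),
        )
        meta = json.loads(f.attrs.get("meta", "{}"))
    return X, y, splits, meta


def save_checkpoint(path, network: Network) -> None:
    """Flat array archive of named parameter tensors plus the model config."""
    arrays = {f"param/{k}": v for k, v in network.parameters().items()}
    with h5py.File(path, "w") as f:
        f.attrs["model_config"] = network.config.to_json()
        for key, arr in arrays.items():
            f.create_dataset(key, data=arr)


def load_checkpoint(path) -> Network:
    with h5py.File(path, "r") as f:
        if "model_config" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'model_config'")
        config = ModelConfig.from_json(f.attrs["model_config"])
        network = build_network(config, seed=0)
        values = {}
        for key in network.parameters():
            dset = f"param/{key}"
            if dset not in f:
                raise FormatError(f"{path}: missing parameter tensor {dset!r}")
            values[key] = f[dset][()]
    network.set_parameters(values)
    return network
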