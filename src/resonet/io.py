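"""Result persistence and config loading.

Trials persist to HDF5 (voltage traces, rasters, metadata), profiles to
CSV, resonance and competition summaries to JSON.  Network and sweep
specifications can be loaded from YAML/JSON config files whose keys
mirror the dataclass fields.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np

from .cells import INParams, LIFParams, PCParams, SynapseParams
from .network import NetworkSpec, SimResult
from .rates import SpikeRaster

__all__ = ["save_result", "load_result", "save_profile", "save_summary",
           "load_network_config", "load_sweep_config"]


def save_result(res: SimResult, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs.update({"dt": res.dt, "v_dt": res.v_dt,
                        "duration": res.duration, "onset": res.onset,
                        "seed": res.seed, "status": res.status,
                        "spec_fingerprint": res.spec_fingerprint})
        for name, raster in res.rasters.items():
            grp = f.create_group(f"raster/{name}")
            grp.attrs["window"] = raster.window
            for i, tr in enumerate(raster.trains):
                grp.create_dataset(str(i), data=np.asarray(tr))
        for name, v in res.v.items():
            f.create_dataset(f"v/{name}", data=v, compression="gzip")


def load_result(path) -> SimResult:
    import h5py

    with h5py.File(path, "r") as f:
        rasters = {}
        for name, grp in f["raster"].items():
            trains = tuple(np.asarray(grp[str(i)])
                           for i in range(len(grp.keys())))
            rasters[name] = SpikeRaster(trains=trains,
                                        window=tuple(grp.attrs["window"]))
        v = {name: np.asarray(d) for name, d in f["v"].items()}
        a = f.attrs
        return SimResult(rasters=rasters, v=v, v_dt=float(a["v_dt"]),
                         dt=float(a["dt"]), duration=float(a["duration"]),
                         onset=float(a["onset"]), seed=int(a["seed"]),
                         status=int(a["status"]))


def save_profile(profile, path) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def save_summary(summary, path) -> None:
    d = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
    Path(path).write_text(json.dumps(d, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not serializable: {type(x)}")


def _build(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**d)


def load_network_config(path) -> NetworkSpec:
    """Build a NetworkSpec from a YAML or JSON file.

    Nested sections ``pc_params``, ``in_params``, ``lif_params``,
    ``ampa``, ``gaba`` map onto the corresponding parameter dataclasses;
    everything else maps onto NetworkSpec fields (``pc_pops`` and
    ``pc_names`` as lists, ``knockout`` as a list of channel names).
    """
    d = _read_config(path)
    sub = {"pc_params": PCParams, "in_params": INParams,
           "lif_params": LIFParams, "ampa": SynapseParams,
           "gaba": SynapseParams}
    kw = {}
    for key, val in d.items():
        if key in sub:
            if key == "pc_params" and "knockout" in val:
                val = dict(val)
                val["knockout"] = tuple(val["knockout"])
            kw[key] = _build(sub[key], val)
        elif key in ("pc_pops", "pc_names"):
            kw[key] = tuple(val)
        else:
            kw[key] = val
    return _build(NetworkSpec, kw)


def load_sweep_config(path, network: NetworkSpec = None):
    from .experiments import SweepSpec

    d = _read_config(path)
    if "network" in d:
        raise ValueError("put the network in its own config file")
    if "grid" in d:
        d["grid"] = tuple(d["grid"])
    if network is not None:
        d["network"] = network
    return _build(SweepSpec, d)


def _read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
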