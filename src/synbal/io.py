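"""Network archives, random fixtures, and serialization helpers.

No community standard exists for rate-network weights, so two dialects are
supported: an HDF5 archive (primary; datasets ``/W_in``, ``/J``, ``/W_out``
plus optional extras, with ``activation``, ``tau`` and ``format_version``
attributes) and a directory of CSV matrices with a JSON metadata file
(secondary, for inspectability).  Round trips are bit-exact for HDF5 and
full double precision for CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .costs import CostMatrix, GainMoments
from .network import Activation, WeightConfig

__all__ = [
    "FORMAT_VERSION",
    "save_network",
    "load_network",
    "random_fixture",
]

FORMAT_VERSION = "1"
_REQUIRED = ("W_in", "J", "W_out")
_KNOWN_EXTRAS = ("costs", "mu", "sigma2", "h")


class ArchiveError(RuntimeError):
    pass


def _pack_extras(extras: dict | None) -> dict:
    """Normalize extras into name -> (array, attrs) pairs."""
    out = {}
    if not extras:
        return out
    for key, value in extras.items():
        if isinstance(value, CostMatrix):
            out["costs"] = (value.c, {"p": value.p, "mode": value.mode})
        elif isinstance(value, GainMoments):
            out["mu"] = (value.mu, {})
            out["sigma2"] = (value.sigma2, {})
        else:
            out[key] = (np.asarray(value), {})
    return out


def save_network(
    path: str | Path,
    config: WeightConfig,
    extras: dict | None = None,
) -> Path:
    """Write a weight configuration (HDF5 or CSV-directory dialect).

    ``extras`` may contain a :class:`CostMatrix` (under any key), a
    :class:`GainMoments`, an ``h`` vector, or arbitrary named arrays; all
    are preserved across a round trip.  A path ending in ``.h5``/``.hdf5``
    selects the HDF5 dialect, anything else a CSV+JSON directory.
    """
    path = Path(path)
    packed = _pack_extras(extras)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["activation"] = config.activation.value
            f.attrs["tau"] = config.tau
            for name in _REQUIRED:
                f.create_dataset(name, data=getattr(config, name))
            for name, (arr, attrs) in packed.items():
                ds = f.create_dataset(name, data=arr)
                for k, v in attrs.items():
                    ds.attrs[k] = v
    else:
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": FORMAT_VERSION,
            "activation": config.activation.value,
            "tau": config.tau,
            "extras": {},
        }
        for name in _REQUIRED:
            np.savetxt(path / f"{name}.csv", getattr(config, name), delimiter=",")
        for name, (arr, attrs) in packed.items():
            np.savetxt(path / f"{name}.csv", np.atleast_2d(arr), delimiter=",")
            meta["extras"][name] = attrs
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def load_network(path: str | Path) -> tuple[WeightConfig, dict]:
    """Load a network archive; returns (config, extras).

    Extras include any cost matrix (as :class:`CostMatrix`), gain moments
    (as :class:`GainMoments`), an ``h`` vector, and any unknown datasets
    verbatim.  Raises :class:`ArchiveError` on a version mismatch or a
    missing required dataset.
    """
    path = Path(path)
    if path.is_file():
        with h5py.File(path, "r") as f:
            version = str(f.attrs.get("format_version", ""))
            if version != FORMAT_VERSION:
                raise ArchiveError(
                    f"unsupported archive version {version!r} "
                    f"(expected {FORMAT_VERSION!r})"
                )
            for name in _REQUIRED:
                if name not in f:
                    raise ArchiveError(f"archive is missing dataset /{name}")
            config = WeightConfig(
                W_in=f["W_in"][()],
                J=f["J"][()],
                W_out=f["W_out"][()],
                activation=str(f.attrs["activation"]),
                tau=float(f.attrs["tau"]),
            )
            raw = {
                name: (f[name][()], dict(f[name].attrs))
                for name in f
                if name not in _REQUIRED
            }
    elif path.is_dir():
        meta = json.loads((path / "meta.json").read_text())
        version = str(meta.get("format_version", ""))
        if version != FORMAT_VERSION:
            raise ArchiveError(
                f"unsupported archive version {version!r} "
                f"(expected {FORMAT_VERSION!r})"
            )
        arrays = {}
        for csv in path.glob("*.csv"):
            arrays[csv.stem] = np.atleast_2d(
                np.loadtxt(csv, delimiter=",", ndmin=2)
            )
        for name in _REQUIRED:
            if name not in arrays:
                raise ArchiveError(f"archive is missing matrix {name}.csv")
        config = WeightConfig(
            W_in=arrays["W_in"],
            J=arrays["J"],
            W_out=arrays["W_out"],
            activation=meta["activation"],
            tau=float(meta["tau"]),
        )
        raw = {
            name: (arr, meta.get("extras", {}).get(name, {}))
            for name, arr in arrays.items()
            if name not in _REQUIRED
        }
    else:
        raise FileNotFoundError(path)

    extras: dict = {}
    if "costs" in raw:
        arr, attrs = raw.pop("costs")
        extras["costs"] = CostMatrix(
            c=arr, p=float(attrs.get("p", 2.0)), mode=str(attrs.get("mode", "custom"))
        )
    if "mu" in raw and "sigma2" in raw:
        mu, _ = raw.pop("mu")
        sigma2, _ = raw.pop("sigma2")
        extras["moments"] = GainMoments(mu=np.ravel(mu), sigma2=np.ravel(sigma2))
    if "h" in raw:
        arr, _ = raw.pop("h")
        extras["h"] = np.ravel(arr)
    for name, (arr, _attrs) in raw.items():
        extras[name] = arr
    return config, extras


def random_fixture(
    N: int,
    density: float = 0.3,
    ensure_strongly_connected: bool = True,
    seed: int = 0,
    n_inputs: int = 2,
    n_outputs: int = 1,
    activation: Activation | str = Activation.RELU,
) -> WeightConfig:
    """Random sparse network with J_ij ~ N(0, 1/N) on present synapses.

    With ``ensure_strongly_connected`` a random Hamiltonian-cycle backbone
    is added so the cost graph of any power-law cost is strongly connected
    regardless of density.  Deterministic per seed.
    """
    if N < 2:
        raise ValueError("need at least two neurons")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(N)
    mask = rng.random((N, N)) < density
    J = np.where(mask, rng.normal(0.0, scale, size=(N, N)), 0.0)
    if ensure_strongly_connected:
        order = rng.permutation(N)
        for src, dst in zip(order, np.roll(order, -1)):
            if J[dst, src] == 0.0:
                val = 0.0
                while val == 0.0:
                    val = rng.normal(0.0, scale)
                J[dst, src] = val
    W_in = rng.normal(0.0, scale, size=(N, n_inputs))
    W_out = rng.normal(0.0, scale, size=(n_outputs, N))
    return WeightConfig(W_in=W_in, J=J, W_out=W_out, activation=activation, tau=1.0)
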