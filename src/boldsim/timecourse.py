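"""Complex signal timecourses produced by the diffusion engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SignalTimecourse:
    """Total / extravascular / intravascular complex signal versus time.

    Times are in ms with one sample per simulation step, t_j = j * dt for
    j = 0 .. n_steps-1, so S(0) = 1 in every populated compartment.  A
    compartment that holds no spins (or grid cells) carries NaN and its
    weight in the total is zero.
    """

    times: np.ndarray            # ms
    s_tot: np.ndarray            # complex
    s_ev: np.ndarray
    s_iv: np.ndarray
    approach: str = ""
    radius: float = np.nan       # um
    voxel_id: int = -1
    seed: int | None = None
    n_ev: int = 0
    n_iv: int = 0
    echoes: dict = field(default_factory=dict)   # e.g. {"GE": 30.0, "SE": 70.0}

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (self.s_tot, self.s_ev, self.s_iv):
            if len(arr) != n:
                raise ValueError("signal arrays must match the time axis")

    def compartment(self, which: str) -> np.ndarray:
        try:
            return {"total": self.s_tot, "ev": self.s_ev,
                    "iv": self.s_iv}[which]
        except KeyError:
            raise ValueError(f"unknown compartment {which!r}") from None

    def index_of_time(self, t_ms: float) -> int:
        i = int(round((t_ms - self.times[0]) / (self.times[1] - self.times[0])))
        if not 0 <= i < len(self.times) or \
                abs(self.times[i] - t_ms) > 1e-9:
            raise ValueError(f"time {t_ms} ms is not on the sampled grid")
        return i

    def at_time(self, t_ms: float, which: str = "total") -> complex:
        return complex(self.compartment(which)[self.index_of_time(t_ms)])

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.times,
            "re_s_tot": self.s_tot.real, "im_s_tot": self.s_tot.imag,
            "re_s_ev": self.s_ev.real, "im_s_ev": self.s_ev.imag,
            "re_s_iv": self.s_iv.real, "im_s_iv": self.s_iv.imag,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "SignalTimecourse":
        df = pd.read_csv(path)
        return cls(times=df["time_ms"].to_numpy(),
                   s_tot=df["re_s_tot"].to_numpy() + 1j * df["im_s_tot"].to_numpy(),
                   s_ev=df["re_s_ev"].to_numpy() + 1j * df["im_s_ev"].to_numpy(),
                   s_iv=df["re_s_iv"].to_numpy() + 1j * df["im_s_iv"].to_numpy(),
                   **meta)

    def to_hdf5(self, path: str | Path, group: str = "/") -> None:
        import h5py
        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for name in ("times", "s_tot", "s_ev", "s_iv"):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=getattr(self, name))
            g.attrs.update({"approach": self.approach, "radius": self.radius,
                            "voxel_id": self.voxel_id,
                            "seed": -1 if self.seed is None else self.seed,
                            "n_ev": self.n_ev, "n_iv": self.n_iv})


def mean_timecourse(courses: list[SignalTimecourse]) -> SignalTimecourse:
    """Voxel-mean of complex signals (complex mean, not magnitude mean)."""
    if not courses:
        raise ValueError("no timecourses to average")
    t = courses[0].times
    first = courses[0]
    return SignalTimecourse(
        times=t.copy(),
        s_tot=np.mean([c.s_tot for c in courses], axis=0),
        s_ev=np.mean([c.s_ev for c in courses], axis=0),
        s_iv=np.mean([c.s_iv for c in courses], axis=0),
        approach=first.approach, radius=first.radius, voxel_id=-1,
        n_ev=sum(c.n_ev for c in courses),
        n_iv=sum(c.n_iv for c in courses),
        echoes=dict(first.echoes))
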