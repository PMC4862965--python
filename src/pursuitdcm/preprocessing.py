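"""Behavioural and sensor-level preprocessing.

Covers the analysis steps between raw (simulated) recordings and model
inversion: saccade masking, per-cycle quality control and averaging of
eye traces; eye-artefact regression with signal-space projection, SVD
subject screening, epoching/baselining and spatial-mode reduction of
multichannel sensor data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SensorEpochs",
    "remove_saccades",
    "cycle_qc",
    "average_and_normalize",
    "regress_out_eye_artefact",
    "subject_svd_screen",
    "epoch_baseline_average",
    "reduce_to_modes",
]

#: saccade velocity criterion (degrees / s)
SACCADE_THRESHOLD_DEG_S = 35.0
#: cycle-QC criterion from the recording geometry (cm on screen);
#: kept as metadata — QC in normalized units uses ``rmse_threshold``
RMSE_THRESHOLD_CM = 5.6


@dataclass
class SensorEpochs:
    """Epoched multichannel sensor data with aligned eye traces.

    data: channels x time x trials; times in ms relative to stimulus
    onset (target emergence from the occluder); labels: per-trial
    condition in {smooth, noisy}; eye: time x trials eye position on the
    same time base.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    eye: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        self.labels = np.asarray(self.labels)
        self.eye = np.asarray(self.eye, float)
        c, t, n = self.data.shape
        if self.times.shape != (t,):
            raise ValueError("times must match the data time axis")
        if self.labels.shape != (n,):
            raise ValueError("labels must match the trial axis")
        if self.eye.shape != (t, n):
            raise ValueError("eye must be time x trials")
        bad = set(np.unique(self.labels)) - {"smooth", "noisy"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    def copy(self) -> "SensorEpochs":
        return SensorEpochs(self.data.copy(), self.times.copy(),
                            self.labels.copy(), self.eye.copy())

    def save_dir(self, path) -> None:
        """Round-trip as a directory of delimited matrices."""
        import os

        os.makedirs(path, exist_ok=True)
        np.savetxt(os.path.join(path, "times.tsv"), self.times,
                   delimiter="\t")
        pd.DataFrame({"label": self.labels}).to_csv(
            os.path.join(path, "labels.tsv"), sep="\t", index=False)
        np.savetxt(os.path.join(path, "eye.tsv"), self.eye, delimiter="\t")
        c, t, n = self.data.shape
        np.savetxt(os.path.join(path, "data.tsv"),
                   self.data.reshape(c, t * n), delimiter="\t",
                   header=f"channels={c} time={t} trials={n}")

    @classmethod
    def load_dir(cls, path) -> "SensorEpochs":
        import os

        times = np.loadtxt(os.path.join(path, "times.tsv"))
        labels = pd.read_csv(os.path.join(path, "labels.tsv"),
                             sep="\t")["label"].to_numpy()
        eye = np.loadtxt(os.path.join(path, "eye.tsv"))
        with open(os.path.join(path, "data.tsv")) as fh:
            header = fh.readline().lstrip("# ").strip()
        dims = dict(kv.split("=") for kv in header.split())
        flat = np.loadtxt(os.path.join(path, "data.tsv"), skiprows=1)
        data = flat.reshape(int(dims["channels"]), int(dims["time"]),
                            int(dims["trials"]))
        if eye.ndim == 1:
            eye = eye[:, None]
        return cls(data, times, labels, eye)


def remove_saccades(
    eye_velocity: np.ndarray,
    threshold: float = SACCADE_THRESHOLD_DEG_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask samples whose |velocity| exceeds the saccade criterion.

    Returns (masked series with NaN at saccadic samples, boolean mask of
    masked samples).  Sub-threshold samples are returned unchanged.
    """
    v = np.asarray(eye_velocity, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity series must be finite")
    mask = np.abs(v) > threshold
    out = v.copy()
    out[mask] = np.nan
    return out, mask


def cycle_qc(
    eye: np.ndarray,
    target: np.ndarray,
    rmse_threshold: float,
    cycle_len: int | None = None,
    boundaries: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cycle RMSE between eye and target with a flagging threshold.

    Cycles are delimited either by a fixed ``cycle_len`` in samples or
    by explicit ``boundaries`` (start indices).  Cycles whose RMSE
    exceeds the threshold are flagged, never dropped — discarding is the
    caller's decision.
    """
    eye = np.asarray(eye, float)
    target = np.asarray(target, float)
    if eye.shape != target.shape:
        raise ValueError("eye and target must be aligned")
    if boundaries is None:
        if cycle_len is None:
            raise ValueError("need cycle_len or boundaries")
        boundaries = np.arange(0, len(eye) - cycle_len + 1, cycle_len)
    rows = []
    for i, start in enumerate(boundaries):
        stop = (boundaries[i + 1] if i + 1 < len(boundaries)
                else len(eye))
        err = eye[start:stop] - target[start:stop]
        rmse = float(np.sqrt(np.mean(err**2)))
        rows.append({"cycle": i, "start": int(start), "stop": int(stop),
                     "rmse": rmse, "flagged": rmse > rmse_threshold})
    return pd.DataFrame(rows)


def average_and_normalize(
    eye_cycles: np.ndarray,
    target_cycles: np.ndarray,
) -> dict:
    """Average aligned single cycles and rescale to unit target amplitude.

    ``eye_cycles``/``target_cycles`` are n_cycles x n_samples arrays of
    already-segmented cycles.  The mean target is scaled so that its
    peak absolute value is 1 and the same scale factor is applied to the
    mean eye trace, so eye and target remain commensurate.
    """
    eye_cycles = np.atleast_2d(np.asarray(eye_cycles, float))
    target_cycles = np.atleast_2d(np.asarray(target_cycles, float))
    if eye_cycles.shape != target_cycles.shape:
        raise ValueError("cycle arrays must be congruent")
    eye_mean = np.nanmean(eye_cycles, axis=0)
    target_mean = np.nanmean(target_cycles, axis=0)
    peak = np.max(np.abs(target_mean))
    if peak == 0:
        raise ValueError("degenerate (all-zero) target cycle")
    scale = 1.0 / peak
    return {
        "eye": eye_mean * scale,
        "target": target_mean * scale,
        "scale": scale,
        "n_cycles": eye_cycles.shape[0],
    }


def regress_out_eye_artefact(
    epochs: SensorEpochs,
    n_components: int = 1,
) -> tuple[SensorEpochs, np.ndarray]:
    """Remove the pursuit artefact by regression + signal-space projection.

    Each channel of the trial-averaged ERF is regressed on the averaged
    eye position; the vector of standardised coefficients (weighted back
    by the channel SDs, i.e. the artefact topography in sensor units)
    defines the spatial component that is projected out of every trial.
    Output dimensions are unchanged; returns (cleaned epochs, the unit
    topography that was removed).

    Only ``n_components = 1`` is meaningful for a single eye regressor;
    the argument is kept for symmetry with multi-regressor variants.
    """
    erf = epochs.data.mean(axis=2)  # channels x time
    eye = epochs.eye.mean(axis=1)
    mean_level = float(np.abs(eye).mean())
    eye = eye - eye.mean()
    if float(np.std(eye)) < 1e-10 * (1.0 + mean_level):
        raise ValueError("degenerate regressor: eye position has no variance")
    var = float(eye @ eye)
    # per-channel regression slope on eye position; multiplied by the
    # eye SD this is the standardised coefficient weighted by the
    # channel SD — proportional to the artefact field map
    beta = (erf - erf.mean(axis=1, keepdims=True)) @ eye / var
    topo = beta * np.sqrt(var / len(eye))
    norm = np.linalg.norm(topo)
    scale = float(np.sqrt(np.mean(erf**2)))
    if norm <= 1e-10 * (1.0 + scale):
        return epochs.copy(), np.zeros_like(topo)
    u = topo / norm
    out = epochs.copy()
    # rank-1 signal-space projection applied to every trial
    proj = np.tensordot(u, out.data, axes=(0, 0))  # time x trials
    out.data = out.data - u[:, None, None] * proj[None, :, :]
    return out, u


def subject_svd_screen(
    mean_topographies: np.ndarray,
    flag_sd: float = 6.0,
) -> dict:
    """SVD screening of per-subject mean sensor topographies.

    Columns (subjects) are normalised to unit sum of squares, the matrix
    is mean-corrected across subjects, and M = U S V^T is decomposed.
    The projection P = M^T U localises each subject along the principal
    spatial axes; subjects whose component-2 coordinate deviates more
    than ``flag_sd`` robust standard deviations (default 6: the MAD of a
    tight inlier cluster underestimates its noise tail, so ordinary
    subjects can reach robust z of 4-5, while genuine minority
    topographies score orders of magnitude higher) are flagged as outliers (e.g. residual artefact topographies).
    """
    M = np.asarray(mean_topographies, float)
    if M.ndim != 2:
        raise ValueError("expected channels x subjects matrix")
    norms = np.sqrt((M**2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("zero topography for some subject")
    M = M / norms
    M = M - M.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    P = M.T @ U  # subjects x components
    # an aberrant (artefact) topography shared by a minority of
    # subjects loads onto one of the two leading components — which
    # one depends on its size relative to ordinary between-subject
    # variability — so both are screened with a robust z-score
    flags = np.zeros(P.shape[0], dtype=bool)
    for k in range(min(2, P.shape[1])):
        if S[k] < 0.1 * S[0]:
            continue  # noise-level component: robust z is meaningless
        comp = P[:, k]
        med = np.median(comp)
        robust_sd = 1.4826 * np.median(np.abs(comp - med))
        if robust_sd > 0:
            flags |= np.abs(comp - med) > flag_sd * robust_sd
    return {
        "projection": P,
        "singular_values": S,
        "components": U,
        "outliers": flags,
    }


def epoch_baseline_average(
    epochs: SensorEpochs,
    baseline: tuple[float, float] = (-300.0, 0.0),
) -> dict[str, np.ndarray]:
    """Mean-correct, baseline-correct and average per condition.

    Each trial is mean-corrected over the whole epoch, then the mean of
    the pre-stimulus ``baseline`` window is subtracted per channel;
    trials are averaged within condition.  Returns a mapping condition
    -> channels x time evoked field; the time base is preserved.
    """
    lo, hi = baseline
    sel = (epochs.times >= lo) & (epochs.times <= hi)
    if not np.any(sel):
        raise ValueError("baseline window outside the epoch")
    d = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    d = d - d[:, sel, :].mean(axis=1, keepdims=True)
    out = {}
    for cond in ("smooth", "noisy"):
        mask = epochs.labels == cond
        if np.any(mask):
            out[cond] = d[:, :, mask].mean(axis=2)
    return out


def reduce_to_modes(
    evoked: np.ndarray,
    n_modes: int = 8,
    times: np.ndarray | None = None,
    fit_window: tuple[float, float] = (0.0, 200.0),
) -> dict:
    """Project an evoked field onto its leading spatial modes.

    The spatial modes are the left singular vectors of the (possibly
    condition-concatenated) channels x time matrix; the projection is
    restricted to the post-stimulus fit window when ``times`` is given.
    Returns the modes x time data, the projector and the retained
    variance fraction.
    """
    evoked = np.asarray(evoked, float)
    if times is not None:
        times = np.asarray(times, float)
        sel = (times >= fit_window[0]) & (times <= fit_window[1])
        windowed = evoked[:, sel]
        out_times = times[sel]
    else:
        windowed = evoked
        out_times = None
    U, S, _ = np.linalg.svd(evoked, full_matrices=False)
    k = min(n_modes, U.shape[1])
    proj = U[:, :k]
    retained = float((S[:k] ** 2).sum() / max((S**2).sum(), 1e-300))
    return {
        "modes": proj.T @ windowed,
        "projector": proj,
        "retained_variance": retained,
        "times": out_times,
    }
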