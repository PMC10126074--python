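"""Acoustic voice features and the standardized 3D voice space.

A speaker's voice is summarized by three acoustic quantities: mean
fundamental frequency (f0, Hz), formant dispersion (FD, Hz; the mean
frequency difference between successive formants F1-F4), and
harmonics-to-noise ratio (HNR, dB).  Voices of one gender stratum are
embedded in a 3D space by z-standardizing each quantity within the
stratum; Euclidean distance in that space is the acoustic similarity
metric used for triplet construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoiceFeatures",
    "VoiceSpace",
    "AcousticBackend",
    "BackendUnavailableError",
    "formant_dispersion",
    "rms_normalize",
    "build_voice_space",
    "aggregate_features",
    "read_feature_table",
    "write_feature_table",
    "load_wav",
]

#: Conventional reference amplitude under which an RMS of 1.0 in unscaled
#: digital audio corresponds to ~94 dB; 60 dB is a comfortable level.
DEFAULT_DB_REFERENCE = 2e-5


class BackendUnavailableError(RuntimeError):
    """Raised when waveform feature extraction is requested without a backend."""


@dataclass(frozen=True)
class VoiceFeatures:
    """Acoustic summary of one speaker.

    Parameters
    ----------
    speaker_id : str
        Opaque identifier.
    gender : str
        Gender stratum label (the speaker pool is stratified, e.g. "f"/"m").
    f0_hz : float
        Mean fundamental frequency over voiced frames, Hz, > 0.
    fd_hz : float
        Formant dispersion, Hz, > 0.  If ``formants_hz`` is given it must
        equal their mean successive difference.
    hnr_db : float
        Mean harmonics-to-noise ratio, dB.
    formants_hz : tuple of 4 floats, optional
        Mean F1..F4 in Hz, strictly increasing.
    """

    speaker_id: str
    gender: str
    f0_hz: float
    fd_hz: float
    hnr_db: float
    formants_hz: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.f0_hz) or self.f0_hz <= 0:
            raise ValueError(f"f0 must be finite and positive, got {self.f0_hz}")
        if not np.isfinite(self.fd_hz) or self.fd_hz <= 0:
            raise ValueError(f"formant dispersion must be positive, got {self.fd_hz}")
        if not np.isfinite(self.hnr_db):
            raise ValueError("HNR must be finite")
        if self.formants_hz is not None:
            fd = formant_dispersion(self.formants_hz)
            if not np.isclose(fd, self.fd_hz, rtol=1e-9, atol=1e-9):
                raise ValueError(
                    f"fd_hz={self.fd_hz} inconsistent with formants (implies {fd})"
                )


def formant_dispersion(formants: Sequence[float]) -> float:
    """Mean frequency difference of successive formants F1 through F4.

    Equals ``(F4 - F1) / 3`` algebraically (telescoping sum).

    Raises
    ------
    ValueError
        If not exactly four finite, strictly increasing values.
    """
    f = np.asarray(formants, dtype=float)
    if f.shape != (4,):
        raise ValueError("exactly four formant frequencies required")
    if not np.all(np.isfinite(f)):
        raise ValueError("formants must be finite")
    if not np.all(np.diff(f) > 0):
        raise ValueError(f"formants must be strictly increasing, got {formants}")
    return float(np.mean(np.diff(f)))


def rms_normalize(
    waveform: np.ndarray,
    target_level_db: float = 60.0,
    reference: float = DEFAULT_DB_REFERENCE,
) -> np.ndarray:
    """Scale a waveform to a target RMS level in dB re ``reference``.

    The output satisfies ``20*log10(rms(out)/reference) == target_level_db``.
    Scaling is a single positive factor, so the operation is idempotent and
    invariant to prior scaling of the input.

    Raises
    ------
    ValueError
        For an all-zero (silent) waveform or non-finite target.
    """
    x = np.asarray(waveform, dtype=float)
    if not np.isfinite(target_level_db):
        raise ValueError("target level must be finite")
    rms = float(np.sqrt(np.mean(np.square(x))))
    if rms == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero waveform")
    target_rms = reference * 10.0 ** (target_level_db / 20.0)
    return x * (target_rms / rms)


@dataclass(frozen=True)
class VoiceSpace:
    """Standardized (f0, FD, HNR) coordinates for one gender stratum.

    ``coords[i]`` is the z-scored 3-vector for ``speaker_ids[i]``.
    ``standardization_params`` records the per-dimension mean/SD (and the
    f0 scale used) so coordinates are reproducible from the raw table.
    """

    stratum: str
    speaker_ids: tuple[str, ...]
    coords: np.ndarray
    standardization_params: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.speaker_ids), 3):
            raise ValueError("coords must be (n_speakers, 3)")

    @property
    def n_speakers(self) -> int:
        return len(self.speaker_ids)

    def index_of(self, speaker_id: str) -> int:
        return self.speaker_ids.index(speaker_id)


def build_voice_space(
    features: Sequence[VoiceFeatures],
    stratum: str | None = None,
    log_f0: bool = False,
) -> VoiceSpace:
    """Embed speakers of one gender stratum in the standardized 3D space.

    Each dimension (f0, FD, HNR) is z-scored within the stratum using the
    sample SD (n-1 denominator).  f0 enters on the raw Hz scale by default;
    ``log_f0=True`` switches to log-Hz before standardization (the choice
    is recorded in ``standardization_params``).

    Parameters
    ----------
    features : sequence of VoiceFeatures
        If ``stratum`` is given, entries of other genders are dropped;
        otherwise all entries must share one gender.
    """
    if stratum is not None:
        features = [f for f in features if f.gender == stratum]
    else:
        genders = {f.gender for f in features}
        if len(genders) > 1:
            raise ValueError(
                f"mixed genders {sorted(genders)}; pass stratum= to select one "
                "(triplets are gender-matched) or build pooled spaces explicitly"
            )
        stratum = next(iter(genders)) if genders else ""
    if len(features) < 3:
        raise ValueError(f"need >= 3 speakers in stratum {stratum!r}, got {len(features)}")
    ids = tuple(f.speaker_id for f in features)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate speaker ids")
    f0 = np.array([f.f0_hz for f in features])
    if log_f0:
        f0 = np.log(f0)
    raw = np.column_stack(
        [f0, [f.fd_hz for f in features], [f.hnr_db for f in features]]
    )
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        dim = ("f0", "fd", "hnr")[int(np.argmin(sd))]
        raise ValueError(f"zero variance in dimension {dim}; cannot standardize")
    params = {
        "dimensions": ("f0", "fd", "hnr"),
        "f0_scale": "log_hz" if log_f0 else "hz",
        "mean": mean.tolist(),
        "sd": sd.tolist(),
        "sd_denominator": "n-1",
    }
    return VoiceSpace(stratum, ids, (raw - mean) / sd, params)


class AcousticBackend(Protocol):
    """Framewise acoustic analyzer contract.

    ``analyze(waveform, rate)`` returns a dict with keys ``f0`` (per-frame
    f0 in Hz over voiced frames only), ``formants`` (frames x 4 array of
    F1..F4 in Hz), and ``hnr`` (per-frame HNR in dB).
    """

    def analyze(self, waveform: np.ndarray, rate: int) -> dict: ...


def aggregate_features(
    waveform: np.ndarray,
    rate: int,
    speaker_id: str,
    gender: str,
    backend: AcousticBackend | None = None,
) -> VoiceFeatures:
    """Aggregate framewise backend output into a :class:`VoiceFeatures`.

    The toolkit defines only the aggregation (time averages of voiced-frame
    f0, of F1..F4 with FD derived, and of HNR); the signal processing lives
    in the pluggable backend.  Without a backend the feature-table input
    path remains fully functional.

    Raises
    ------
    BackendUnavailableError
        If no backend is supplied.
    ValueError
        If the recording is not mono or the backend reports no voiced frames.
    """
    x = np.asarray(waveform)
    if x.ndim != 1:
        raise ValueError("mono recording required")
    if backend is None:
        raise BackendUnavailableError(
            "no acoustic backend configured; supply framewise features or use "
            "the feature-table (CSV) input path"
        )
    frames = backend.analyze(x, rate)
    f0 = np.asarray(frames["f0"], dtype=float)
    if f0.size == 0:
        raise ValueError("no voiced frames; cannot aggregate f0")
    formants = np.atleast_2d(np.asarray(frames["formants"], dtype=float))
    mean_formants = tuple(formants.mean(axis=0))
    return VoiceFeatures(
        speaker_id=speaker_id,
        gender=gender,
        f0_hz=float(f0.mean()),
        fd_hz=formant_dispersion(mean_formants),
        hnr_db=float(np.mean(frames["hnr"])),
        formants_hz=mean_formants,  # type: ignore[arg-type]
    )


def load_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as a float mono waveform in [-1, 1] plus its rate.

    Integer PCM is scaled by its full-scale value; multi-channel input is
    rejected (recordings are mono).
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("mono WAV required")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(rate)


_TABLE_COLUMNS = ["speaker_id", "gender", "f0_hz", "f1_hz", "f2_hz", "f3_hz", "f4_hz", "hnr_db"]


def read_feature_table(path) -> list[VoiceFeatures]:
    """Read a voice feature CSV.

    Expected columns: ``speaker_id, gender, f0_hz, hnr_db`` plus either
    ``f1_hz..f4_hz`` (FD computed) or a direct ``fd_hz`` column.
    """
    df = pd.read_csv(path, dtype={"speaker_id": str, "gender": str})
    has_formants = all(c in df.columns for c in ("f1_hz", "f2_hz", "f3_hz", "f4_hz"))
    if not has_formants and "fd_hz" not in df.columns:
        raise ValueError("need either f1_hz..f4_hz columns or an fd_hz column")
    out = []
    for row in df.itertuples(index=False):
        if has_formants:
            formants = (row.f1_hz, row.f2_hz, row.f3_hz, row.f4_hz)
            fd = formant_dispersion(formants)
        else:
            formants, fd = None, float(row.fd_hz)
        out.append(
            VoiceFeatures(
                speaker_id=str(row.speaker_id),
                gender=str(row.gender),
                f0_hz=float(row.f0_hz),
                fd_hz=fd,
                hnr_db=float(row.hnr_db),
                formants_hz=formants,
            )
        )
    return out


def write_feature_table(features: Sequence[VoiceFeatures], path) -> None:
    rows = []
    for f in features:
        row = {
            "speaker_id": f.speaker_id,
            "gender": f.gender,
            "f0_hz": f.f0_hz,
            "hnr_db": f.hnr_db,
            "fd_hz": f.fd_hz,
        }
        if f.formants_hz is not None:
            row.update(
                {f"f{i+1}_hz": v for i, v in enumerate(f.formants_hz)}
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
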