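"""Synthetic multimodal cohorts with controllable signal and redundancy.

The generator emulates the *statistical structure* the pipeline assumes —
one latent severity per patient that leaks, with per-source strength β_s
and inter-source redundancy ρ, into every modality — without attempting
clinical realism in vital-sign dynamics, note language or radiographic
appearance.

Per patient, a latent risk z ~ N(0, 1) is drawn; each source s observes
u_s = ρ·z + (1−ρ)·ε_s with ε_s ~ N(0, 1).  Time-series values drift by
β_s·u_s, note token frequencies shift with β_s·u_s, and image brightness
shifts with the (shared) vision latent.  Outcomes follow a probit threshold
on z so the 48 h mortality prevalence matches the configured rate in
expectation.  Everything is reproducible from (config, seed).

Deterministic stub encoders stand in for the pretrained text and image
networks at test time; they honor the same contracts (768-dim text vectors;
18 probabilities + 1024 dense features per 224×224 image) and are sensitive
to input content, so information injected upstream survives to the fusion
embedding.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .patient_record import ImageStudy, NoteDocument, PatientFile
from .registry import TIMESERIES_SIGNALS, SourceRegistry
from .tasks import PATHOLOGIES, TaskSpec, label_samples

_ADMIT_EPOCH = datetime(2000, 1, 1)

_FILLER_WORDS = (
    "patient", "noted", "stable", "exam", "course", "plan", "status",
    "overnight", "review", "continued", "monitor", "daily", "unit",
    "transfer", "family", "consult", "home", "repeat", "study", "pending",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``signal_strength`` (β_s) scales how strongly each source's observations
    reflect its latent; ``redundancy`` (ρ) is the shared fraction of the
    patient latent across sources (ρ→1 makes sources near-copies, the regime
    in which adding sources yields diminishing returns).  ``prevalence`` is
    the per-stay 48 h mortality rate; ``label_noise_sd`` adds probit noise
    between the latent and the outcome (0 makes the outcome a deterministic
    threshold on z, hence separable given noiseless features).
    """

    n_patients: int = 200
    stays_per_patient: int = 1
    sources: tuple[str, ...] = (
        "de", "ce", "le", "pe", "radn", "ecgn", "econ", "vp", "vd", "vmp", "vmd",
    )
    signal_strength: Union[float, Mapping[str, float]] = 1.0
    redundancy: float = 0.3
    event_rate: float = 0.5          # events per hour per signal
    mean_note_tokens: int = 250
    image_size: tuple[int, int] = (48, 48)
    n_image_studies: int = 1
    images_per_study: int = 1
    prevalence: float = 0.15
    label_noise_sd: float = 1.0
    observation_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.stays_per_patient < 1:
            raise ValueError("cohort sizes must be positive")
        if not (0.0 <= self.redundancy <= 1.0):
            raise ValueError("redundancy must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        for rate_name in ("event_rate", "label_noise_sd", "observation_noise_sd"):
            if getattr(self, rate_name) < 0:
                raise ValueError(f"{rate_name} must be >= 0")
        if self.n_image_studies < 1 or self.images_per_study < 1:
            raise ValueError("each stay needs at least one image")

    def beta(self, source: str) -> float:
        if isinstance(self.signal_strength, Mapping):
            b = float(self.signal_strength.get(source, 0.0))
        else:
            b = float(self.signal_strength)
        if b < 0:
            raise ValueError("signal strengths must be >= 0")
        return b


# ---------------------------------------------------------------------------
# deterministic encoder stubs
# ---------------------------------------------------------------------------

def _seed_from(*parts: str) -> int:
    digest = hashlib.blake2b("\x1f".join(parts).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**63)


class StubTextEncoder:
    """Hash-then-average token embedding: deterministic, content-sensitive.

    Each token maps (via a salted hash) to a fixed 768-vector; a chunk's
    embedding is the mean of its token vectors.  Synthetic note token
    frequencies therefore translate linearly into embedding coordinates.
    """

    max_tokens = 512
    output_dim = 768

    def __init__(self, seed: int = 0):
        self._salt = f"text-stub-{int(seed)}"
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            rng = np.random.default_rng(_seed_from(self._salt, token))
            vec = rng.standard_normal(self.output_dim)
            self._cache[token] = vec
        return vec

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros(self.output_dim)
        return np.mean([self._token_vector(t) for t in tokens], axis=0)


class StubImageModel:
    """Pooled-statistics image encoder honoring the CNN plug-in contract.

    A 224×224 input is summarized by 27 pooled statistics (global moments,
    quantiles, row/column band means, gradient energy), then projected by
    fixed seeded random maps into an 18-dim probability vector (through a
    sigmoid) and a 1024-dim dense vector (through tanh).
    """

    input_size = (224, 224)
    prob_dim = 18
    dense_dim = 1024
    _n_features = 27

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(_seed_from(f"image-stub-{int(seed)}"))
        scale = 1.0 / math.sqrt(self._n_features)
        self._w_prob = rng.standard_normal((self.prob_dim, self._n_features)) * scale
        self._w_dense = rng.standard_normal((self.dense_dim, self._n_features)) * scale

    def _features(self, image: np.ndarray) -> np.ndarray:
        a = np.asarray(image, dtype=np.float64) / 255.0
        rows = a.reshape(8, a.shape[0] // 8, -1).mean(axis=(1, 2))
        cols = a.reshape(-1, 8, a.shape[1] // 8).mean(axis=(0, 2))
        grad = float(np.mean(np.abs(np.diff(a, axis=0)))) if a.shape[0] > 1 else 0.0
        feats = np.concatenate([
            [a.mean(), a.std(), a.min(), a.max()],
            np.quantile(a, [0.1, 0.25, 0.5, 0.75, 0.9]),
            rows,
            cols,
            [float(np.mean(a * a)), grad],
        ])
        return feats - 0.5

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        image = np.asarray(image, dtype=np.float64)
        if image.shape != self.input_size:
            raise ValueError(
                f"stub image model expects {self.input_size}, got {image.shape}"
            )
        f = self._features(image)
        probs = 1.0 / (1.0 + np.exp(-4.0 * (self._w_prob @ f)))
        dense = np.tanh(self._w_dense @ f)
        return probs, dense


def stub_text_encoder(seed: int = 0) -> StubTextEncoder:
    return StubTextEncoder(seed=seed)


def stub_image_model(seed: int = 0) -> StubImageModel:
    return StubImageModel(seed=seed)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Generated patient files plus the conditions that produced them."""

    files: list[PatientFile]
    config: SimulationConfig
    seed: int

    def label_table(self, task: TaskSpec) -> pd.DataFrame:
        return label_samples(self.files, task)


def _signal_base(signal: str, index: int) -> float:
    # arbitrary but fixed per-signal baseline so signals are not identical
    return 50.0 + 5.0 * index


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_cohort(config: SimulationConfig, seed: int = 0) -> Cohort:
    """Generate a cohort of validated :class:`PatientFile` records.

    Deterministic given (config, seed): the same inputs produce
    byte-identical containers when saved.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 2718])
    rho = config.redundancy
    sigma_obs = config.observation_noise_sd
    sigma_lab = config.label_noise_sd
    # probit threshold giving the configured mortality prevalence exactly
    c = norm.ppf(1.0 - config.prevalence) * math.sqrt(1.0 + sigma_lab**2)

    image_sources = [s for s in config.sources if s in ("vp", "vd", "vmp", "vmd")]
    beta_img = (
        float(np.mean([config.beta(s) for s in image_sources]))
        if image_sources
        else 0.0
    )
    h, w = config.image_size
    base_pattern = np.linspace(80.0, 160.0, h)[:, None] * np.ones((1, w))

    files: list[PatientFile] = []
    for p_idx in range(config.n_patients):
        patient_id = f"p{p_idx:05d}"
        z = rng.standard_normal()
        for s_idx in range(config.stays_per_patient):
            stay_id = f"{patient_id}-s{s_idx}"
            admit = _ADMIT_EPOCH + timedelta(
                days=p_idx * config.stays_per_patient + s_idx
            )
            u = {
                s: rho * z + (1.0 - rho) * rng.standard_normal()
                for s in config.sources
            }
            u_img = rho * z + (1.0 - rho) * rng.standard_normal()

            # ---- observation window: studies in (12, 20) h, events before
            t_obs = 20.0
            study_times = np.sort(rng.uniform(12.0, t_obs, config.n_image_studies))

            # demographics
            demo_rng_age = rng.standard_normal()
            if "de" in config.sources:
                age = 60.0 + 10.0 * config.beta("de") * u["de"] + 3.0 * sigma_obs * demo_rng_age
            else:
                age = 60.0 + 12.0 * demo_rng_age
            demographics = {
                "age": float(np.clip(age, 18.0, 95.0)),
                "sex_code": float(rng.integers(0, 2)),
                "ethnicity_code": float(rng.integers(0, 8)),
                "marital_status_code": float(rng.integers(0, 5)),
                "language_code": float(rng.integers(0, 2)),
                "insurance_code": float(rng.integers(0, 5)),
            }

            # time-series event tables
            event_tables: dict[str, pd.DataFrame] = {}
            for source, signals in TIMESERIES_SIGNALS.items():
                if source not in config.sources:
                    continue
                shift = 10.0 * config.beta(source) * u[source]
                recs = []
                for j, sig in enumerate(signals):
                    if sigma_obs > 0:
                        n_events = rng.poisson(config.event_rate * t_obs)
                        times = np.sort(rng.uniform(0.0, t_obs, n_events))
                        noise = sigma_obs * rng.standard_normal(n_events)
                    else:
                        # zero observation noise ⇒ deterministic sampling
                        # grid too, so features are exact functions of u_s
                        n_events = max(1, round(config.event_rate * t_obs))
                        times = np.linspace(0.0, t_obs, n_events)
                        noise = np.zeros(n_events)
                    vals = _signal_base(sig, j) + shift + noise
                    recs.extend(zip([sig] * n_events, times, vals))
                event_tables[source] = pd.DataFrame(
                    recs, columns=["signal_name", "time_hours", "value"]
                ).astype({"signal_name": str, "time_hours": float, "value": float})

            # free-text notes: token mixture whose composition tracks u_s
            notes: dict[str, list[NoteDocument]] = {}
            for source in ("radn", "ecgn", "econ"):
                if source not in config.sources:
                    continue
                p_crit = _sigmoid(1.5 * config.beta(source) * u[source])
                n_tok = int(rng.poisson(config.mean_note_tokens)) + 1
                fillers = rng.random(n_tok) < 0.3
                crits = rng.random(n_tok) < p_crit
                filler_ids = rng.integers(0, len(_FILLER_WORDS), n_tok)
                tokens = [
                    _FILLER_WORDS[filler_ids[i]]
                    if fillers[i]
                    else ("crit" if crits[i] else "routine")
                    for i in range(n_tok)
                ]
                notes[source] = [
                    NoteDocument(
                        time_hours=float(rng.uniform(1.0, 12.0)),
                        text=" ".join(tokens),
                    )
                ]

            # image studies: brightness carries the vision latent
            studies = []
            for t_img in study_times:
                images = []
                for _ in range(config.images_per_study):
                    img = (
                        base_pattern
                        + 40.0 * beta_img * u_img
                        + 10.0 * sigma_obs * rng.standard_normal((h, w))
                    )
                    images.append(np.clip(img, 0.0, 255.0).astype(np.uint8))
                studies.append(
                    ImageStudy(time_hours=float(t_img), images=tuple(images))
                )

            # outcomes: probit threshold on the latent risk
            dies = z + sigma_lab * rng.standard_normal() > c
            death_time = discharge_time = None
            if dies:
                death_hours = 25.0 + 22.0 * rng.uniform()        # within (24, 72]
                death_time = admit + timedelta(hours=death_hours)
            else:
                los_extra = max(
                    2.0,
                    40.0 + 25.0 * z + 15.0 * sigma_lab * rng.standard_normal(),
                )
                discharge_time = admit + timedelta(hours=24.0 + los_extra)

            # pathology ground truth driven by the vision latent
            ground_truth: dict[str, int] = {}
            for pathology in PATHOLOGIES:
                roll = rng.random()
                score = 1.2 * u_img + 0.8 * rng.standard_normal()
                if roll < 0.10:
                    continue                 # not explored → key absent
                if roll < 0.20:
                    ground_truth[pathology] = -1
                else:
                    ground_truth[pathology] = int(score > 0.3)

            files.append(
                PatientFile(
                    patient_id=patient_id,
                    stay_id=stay_id,
                    admit_time=admit,
                    discharge_time=discharge_time,
                    death_time=death_time,
                    demographics=demographics,
                    event_tables=event_tables,
                    notes=notes,
                    image_studies=studies,
                    pathology_ground_truth=ground_truth,
                )
            )
    return Cohort(files=files, config=config, seed=int(seed))
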