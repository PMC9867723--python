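"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-group (PD vs HC) in-vitro T-cell activation
time course measured on single-channel arrays: 5 donors per group sampled at
0, 2, 4, 8, 12 and 24 h, with one missing donor/time combination, batch
structure, shared activation-marker kinetics and spiked group-differential
signal.  Raw intensities follow the normexp convolution the preprocessing
stage assumes:

    raw = background + amplitude * 2**latent

with a normal background, a per-feature exponential amplitude (the abundance
scale of the transcript), and a latent log2 term collecting activation
kinetics, group effects, batch offsets and log-normal measurement noise.
Group effects therefore enter multiplicatively on the signal component, and
preprocessing must undo the background before they are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortDesign, ExpressionMatrix, SchemaError

#: Time windows of the activation course (hours).
WINDOWS: dict[str, tuple[float, ...]] = {
    "early": (0.0, 2.0),
    "intermediary": (4.0, 8.0),
    "late": (12.0, 24.0),
}

SIGNAL_CLASSES = (
    "activation_shared",
    "group_up",
    "group_down",
    "mixed_direction",
    "mirna_coupled",
    "null",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort dimensions and noise model for :func:`generate_cohort`.

    Defaults follow the study design being emulated (2 groups x 5 donors x
    6 time points) at a scaled-down feature count; the full 30,158-feature
    design is supported but not the default.  ``noise_sd`` is the log2-scale
    residual SD per observation; ``background_mean``/``background_sd``
    parametrise the normal background component and ``signal_rate`` the mean
    of the exponential amplitude distribution.
    """

    n_features: int = 2000
    n_mirnas: int = 200
    donors_per_group: int = 5
    time_points_h: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    n_batches: int = 2
    noise_sd: float = 0.4
    background_mean: float = 50.0
    background_sd: float = 5.0
    signal_rate: float = 1000.0
    batch_sd: float = 0.2
    activation_tau_h: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0 or self.donors_per_group <= 0 or self.n_batches <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_mirnas < 0:
            raise ValueError("n_mirnas must be non-negative")
        tp = tuple(float(t) for t in self.time_points_h)
        if tp[0] != 0.0:
            raise ValueError("time_points_h must include 0 as the first point")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points_h must be strictly increasing")
        if self.noise_sd <= 0 or self.signal_rate <= 0 or self.background_sd < 0:
            raise ValueError("noise_sd and signal_rate must be > 0, background_sd >= 0")
        object.__setattr__(self, "time_points_h", tp)

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_features)]

    def mirna_ids(self) -> list[str]:
        return [f"MIR{i:04d}" for i in range(self.n_mirnas)]

    def feature_ids(self) -> list[str]:
        return self.gene_ids() + self.mirna_ids()


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth signal assigned to one feature.

    ``effect_log2fc`` is the group (PD minus HC) shift in latent log2
    expression inside ``active_window``; for ``activation_shared`` it is the
    plateau height of the activation ramp shared by both groups.  A
    ``mirna_coupled`` spec couples a miRNA to ``partner_id`` with the
    opposite-signed effect, producing anti-correlated group-difference
    profiles.
    """

    feature_id: str
    signal_class: str
    effect_log2fc: float = 0.0
    active_window: tuple[str, ...] = ()
    partner_id: str | None = None

    def __post_init__(self) -> None:
        if self.signal_class not in SIGNAL_CLASSES:
            raise ValueError(f"unknown signal class {self.signal_class!r}")
        if (self.effect_log2fc == 0.0) != (self.signal_class == "null"):
            raise ValueError("effect_log2fc must be 0 iff signal_class is 'null'")
        if (self.partner_id is not None) != (self.signal_class == "mirna_coupled"):
            raise ValueError("partner_id must be set iff signal_class is 'mirna_coupled'")
        unknown = set(self.active_window) - set(WINDOWS)
        if unknown:
            raise ValueError(f"unknown windows {sorted(unknown)}")


def _window_times(windows: tuple[str, ...]) -> set[float]:
    times: set[float] = set()
    for w in windows:
        times.update(WINDOWS[w])
    return times


def _group_effect_profile(spec: SignalSpec, time_points: tuple[float, ...]) -> np.ndarray:
    """PD-minus-HC latent shift at each time point implied by one spec."""
    prof = np.zeros(len(time_points))
    if spec.signal_class in ("group_up", "group_down", "mirna_coupled"):
        active = _window_times(spec.active_window)
        for j, t in enumerate(time_points):
            if t in active:
                prof[j] = spec.effect_log2fc
    elif spec.signal_class == "mixed_direction":
        # Alternating sign across the spec's windows (first window keeps the
        # sign of effect_log2fc, subsequent windows flip it).
        for k, w in enumerate(spec.active_window):
            sign = 1.0 if k % 2 == 0 else -1.0
            for j, t in enumerate(time_points):
                if t in WINDOWS[w]:
                    prof[j] = sign * spec.effect_log2fc
    return prof


def latent_group_difference(
    spec: SignalSpec, config: SimulationConfig
) -> np.ndarray:
    """Noise-free per-timepoint PD-minus-HC latent profile for one feature."""
    return _group_effect_profile(spec, config.time_points_h)


def generate_cohort(
    config: SimulationConfig,
    signals: list[SignalSpec] | None = None,
) -> tuple[ExpressionMatrix, CohortDesign, pd.DataFrame]:
    """Simulate a raw-intensity cohort plus its design and truth table.

    Returns the raw-stage expression matrix (genes then miRNAs as rows, one
    column per donor/time sample), the cohort design and the truth table of
    signal specs (one row per non-null spec, echoed verbatim for recovery
    tests).  Bit-reproducible for a fixed ``config.seed``.
    """
    signals = list(signals or [])
    feature_ids = config.feature_ids()
    feature_set = set(feature_ids)
    seen: set[str] = set()
    for spec in signals:
        if spec.feature_id not in feature_set:
            raise SchemaError(f"signal references unknown feature {spec.feature_id!r}")
        if spec.feature_id in seen:
            raise SchemaError(f"duplicate signal for feature {spec.feature_id!r}")
        seen.add(spec.feature_id)
        if spec.partner_id is not None:
            if spec.partner_id not in feature_set:
                raise SchemaError(f"unknown partner id {spec.partner_id!r}")
            if spec.partner_id == spec.feature_id:
                raise SchemaError("partner_id must differ from feature_id")

    rng = np.random.default_rng(config.seed)
    tp = np.asarray(config.time_points_h)
    n_feat = len(feature_ids)

    # --- design ------------------------------------------------------------
    rows = []
    for group in ("PD", "HC"):
        for d in range(1, config.donors_per_group + 1):
            donor = f"{'P' if group == 'PD' else 'C'}{d}"
            batch = f"B{(d - 1) % config.n_batches + 1}"
            for t in tp:
                sid = f"{donor}_{t:g}h"
                rows.append((sid, donor, group, float(t), batch))
    design_df = pd.DataFrame(
        rows, columns=["sample_id", "donor", "group", "time_h", "batch"]
    ).set_index("sample_id")
    design = CohortDesign(design_df)
    n_samp = len(design_df)

    # --- latent log2 expression -------------------------------------------
    amplitude = rng.exponential(scale=config.signal_rate, size=n_feat)
    batch_levels = sorted(design_df["batch"].unique())
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(n_feat, len(batch_levels)))
    noise = rng.normal(0.0, config.noise_sd, size=(n_feat, n_samp))

    latent = np.zeros((n_feat, n_samp))
    fid_index = {fid: i for i, fid in enumerate(feature_ids)}
    t_of = design_df["time_h"].to_numpy()
    is_pd = (design_df["group"] == "PD").to_numpy()
    batch_col = np.array([batch_levels.index(b) for b in design_df["batch"]])

    ramp = 1.0 - np.exp(-t_of / config.activation_tau_h)  # saturating up-ramp
    for spec in signals:
        i = fid_index[spec.feature_id]
        if spec.signal_class == "activation_shared":
            latent[i] += spec.effect_log2fc * ramp
        else:
            prof = _group_effect_profile(spec, config.time_points_h)
            shift = np.zeros(n_samp)
            for j, t in enumerate(config.time_points_h):
                shift[(t_of == t) & is_pd] = prof[j]
            latent[i] += shift
            if spec.partner_id is not None:
                prof_p = -prof  # partner carries the opposite-signed effect
                shift_p = np.zeros(n_samp)
                for j, t in enumerate(config.time_points_h):
                    shift_p[(t_of == t) & is_pd] = prof_p[j]
                latent[fid_index[spec.partner_id]] += shift_p

    latent += batch_offsets[:, batch_col]
    latent += noise

    background = rng.normal(config.background_mean, config.background_sd, size=(n_feat, n_samp))
    np.maximum(background, 1e-6, out=background)  # intensities are strictly positive
    raw = background + amplitude[:, None] * np.exp2(latent)

    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=pd.Index(feature_ids, name="feature_id"), columns=design_df.index),
        stage="raw",
    )
    truth = signals_to_frame(signals)
    return matrix, design, truth


def signals_to_frame(signals: list[SignalSpec]) -> pd.DataFrame:
    records = []
    for s in signals:
        records.append(
            {
                "feature_id": s.feature_id,
                "signal_class": s.signal_class,
                "effect_log2fc": s.effect_log2fc,
                "active_window": "+".join(s.active_window),
                "partner_id": s.partner_id if s.partner_id is not None else "",
            }
        )
    return pd.DataFrame(
        records,
        columns=["feature_id", "signal_class", "effect_log2fc", "active_window", "partner_id"],
    )


def frame_to_signals(truth: pd.DataFrame) -> list[SignalSpec]:
    specs = []
    for _, row in truth.iterrows():
        window = tuple(w for w in str(row["active_window"]).split("+") if w)
        partner = row["partner_id"] if isinstance(row["partner_id"], str) and row["partner_id"] else None
        specs.append(
            SignalSpec(
                feature_id=row["feature_id"],
                signal_class=row["signal_class"],
                effect_log2fc=float(row["effect_log2fc"]),
                active_window=window,
                partner_id=partner,
            )
        )
    return specs


def drop_sample(
    matrix: ExpressionMatrix, design: CohortDesign, donor: str, time_h: float
) -> tuple[ExpressionMatrix, CohortDesign]:
    """Remove one donor/time column, emulating a failed sample.

    All downstream group statistics are then computed over the remaining
    samples; dropping an absent column is an error.
    """
    tab = design.table
    mask = (tab["donor"] == donor) & (tab["time_h"] == float(time_h))
    if not mask.any():
        raise SchemaError(f"no sample for donor {donor!r} at {time_h} h")
    sid = tab.index[mask][0]
    new_design = CohortDesign(tab.drop(index=sid))
    new_matrix = ExpressionMatrix(matrix.data.drop(columns=sid), stage=matrix.stage)
    return new_matrix, new_design


# ---------------------------------------------------------------------------
# Signal-list builders used by tests, the CLI and the acceptance script.
# ---------------------------------------------------------------------------

def activation_marker_signals(
    config: SimulationConfig, n_markers: int = 3, plateau_log2: float = 2.0
) -> list[SignalSpec]:
    """Activation markers rising identically in both groups (CD69-like)."""
    ids = config.gene_ids()[:n_markers]
    return [
        SignalSpec(fid, "activation_shared", effect_log2fc=plateau_log2)
        for fid in ids
    ]


def spike_signals(
    config: SimulationConfig,
    n_up: int = 50,
    n_down: int = 50,
    effect_log2fc: float = 2.0,
    window: tuple[str, ...] = ("early",),
    start: int = 10,
) -> list[SignalSpec]:
    """Group-differential spikes of known size in a given time window."""
    ids = config.gene_ids()[start : start + n_up + n_down]
    if len(ids) < n_up + n_down:
        raise ValueError("not enough features for the requested spikes")
    specs = [
        SignalSpec(fid, "group_up", effect_log2fc=abs(effect_log2fc), active_window=window)
        for fid in ids[:n_up]
    ]
    specs += [
        SignalSpec(fid, "group_down", effect_log2fc=-abs(effect_log2fc), active_window=window)
        for fid in ids[n_up:]
    ]
    return specs


def coupled_pair_signals(
    config: SimulationConfig,
    n_pairs: int = 50,
    effect_log2fc: float = 2.0,
    gene_start: int = 1000,
) -> list[SignalSpec]:
    """miRNA/target pairs with opposite-signed effects in cycling windows."""
    mirnas = config.mirna_ids()[:n_pairs]
    genes = config.gene_ids()[gene_start : gene_start + n_pairs]
    if len(mirnas) < n_pairs or len(genes) < n_pairs:
        raise ValueError("not enough miRNAs or genes for the requested pairs")
    window_cycle = [("early",), ("intermediary",), ("late",), ("early", "intermediary")]
    specs = []
    for k, (m, g) in enumerate(zip(mirnas, genes)):
        sign = 1.0 if k % 2 == 0 else -1.0
        specs.append(
            SignalSpec(
                m,
                "mirna_coupled",
                effect_log2fc=sign * abs(effect_log2fc),
                active_window=window_cycle[k % len(window_cycle)],
                partner_id=g,
            )
        )
    return specs


def default_signals(config: SimulationConfig) -> list[SignalSpec]:
    """Default fixture: activation markers, FC spikes, coupled miRNA pairs."""
    specs = activation_marker_signals(config)
    specs += spike_signals(config)
    if config.n_mirnas >= 50 and config.n_features >= 1050:
        specs += coupled_pair_signals(config)
    return specs


def synthetic_target_table(truth: pd.DataFrame, n_weak: int = 20) -> pd.DataFrame:
    """Validated-target table (synthetic) derived from coupled-pair truth.

    Each simulated miRNA/partner pair becomes a "strong"-evidence row; a few
    additional pairs between coupled miRNAs and unrelated genes are written
    with "weak" evidence so evidence-tier filtering is exercised.
    """
    coupled = truth[truth["signal_class"] == "mirna_coupled"]
    rows = [
        {"mirna_id": r.feature_id, "gene_id": r.partner_id, "evidence": "strong"}
        for r in coupled.itertuples(index=False)
    ]
    mirnas = coupled["feature_id"].tolist()
    partners = coupled["partner_id"].tolist()
    for i in range(min(n_weak, len(mirnas) - 1)):
        rows.append(
            {"mirna_id": mirnas[i], "gene_id": partners[(i + 1) % len(partners)],
             "evidence": "weak"}
        )
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence"])


def synthetic_gene_sets(
    config: SimulationConfig,
    truth: pd.DataFrame,
    n_decoys: int = 50,
    decoy_size: int = 50,
    rng: np.random.Generator | None = None,
):
    """Synthetic GMT-style collection: spike-derived sets plus random decoys.

    The "UP_SPIKES" / "DOWN_SPIKES" sets collect the group-differential
    spike features, so enrichment of recovered core genes is testable
    against ground truth; decoy sets are random draws from the gene universe.
    """
    from .enrichment import GeneSetCollection  # local import to avoid a cycle

    rng = rng or np.random.default_rng(config.seed + 7)
    genes = np.array(config.gene_ids())
    sets: dict[str, list[str]] = {}
    up = truth.loc[truth["signal_class"] == "group_up", "feature_id"].tolist()
    down = truth.loc[truth["signal_class"] == "group_down", "feature_id"].tolist()
    if up:
        sets["UP_SPIKES"] = up
    if down:
        sets["DOWN_SPIKES"] = down
    for i in range(n_decoys):
        sets[f"DECOY_{i:03d}"] = list(rng.choice(genes, size=decoy_size, replace=False))
    return GeneSetCollection(sets, source_tag="synthetic")


def write_fixture(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    truth: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write matrix/design/truth TSVs that round-trip through :mod:`tck.io`."""
    from . import io as tck_io  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "design": directory / "design.tsv",
        "truth": directory / "truth.tsv",
    }
    tck_io.write_matrix(matrix, paths["matrix"])
    tck_io.write_design(design, paths["design"])
    tck_io.write_table(truth, paths["truth"])
    return paths
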