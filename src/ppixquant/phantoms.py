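"""Forward simulator of a tissue-mimicking phantom panel.

The generator emulates gelatin phantoms whose optical agents are intralipid
(IL, scattering) and haemoglobin (Hb, absorption) and whose fluorophore is
PpIX in two photochemical emission states.  The default design is the full
factorial crossing of IL in {1, 3, 5} %, Hb in {0.5, 1.25, 2} mg/ml and
PpIX in {0, 5, 10, 15} ug/ml with 3 replicates each -- a 108-sample panel.

Each sample is simulated as:

* a diffuse reflectance spectrum ``R = mu_s' / (mu_s' + mu_a)`` with the
  absorption template shaped like haemoglobin (dominant Soret band near
  415 nm, weaker Q bands at 540/576 nm) and scattering following the mixed
  Rayleigh-Mie power law -- a deliberately simple albedo-like surrogate,
  not a radiative-transport solution;
* a clean emission spectrum mixing the two PpIX states (620-state fraction
  set by a monotone composition rule, with a reduced quantum efficiency for
  the 620 state), an IL/gelatin background hump, and a sharp 690 nm
  instrumental spike whose amplitude scales with IL;
* a multiplicative optical distortion ``R_ex * R(lam)**alpha_true`` -- the
  exact inverse of the spectral correction, so exponent recovery is
  well-posed;
* Poisson counting noise at a configurable expected peak count.

Ground-truth total PpIX concentrations and per-component amplitudes are
returned alongside the observed spectra, so every pipeline stage can be
validated without measured data.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .correction import band_average_reflectance, DEFAULT_EX_BAND
from .optics import ScatteringFitParams, eval_rayleigh_mie
from .quantify import PpixTemplate
from .spectra import (
    ReflectanceRecord,
    SpectraMatrix,
    WavelengthGrid,
    load_concentrations,
    load_spectra,
    reflectance_records,
    write_concentrations,
    write_spectra,
)
from .unmixing import make_noise_endmember

__all__ = [
    "DEFAULT_IL_LEVELS",
    "DEFAULT_HB_LEVELS",
    "DEFAULT_PPIX_LEVELS",
    "ForwardModelParams",
    "PhantomDataset",
    "generate_design",
    "default_state_fraction",
    "background_endmember",
    "simulate_reflectance",
    "simulate_emission",
    "simulate_dataset",
    "average_replicates",
    "write_dataset",
    "load_dataset",
    "reflectance_grid",
]

DEFAULT_IL_LEVELS = (1.0, 3.0, 5.0)
DEFAULT_HB_LEVELS = (0.5, 1.25, 2.0)
DEFAULT_PPIX_LEVELS = (0.0, 5.0, 10.0, 15.0)
DEFAULT_REPLICATES = 3


def reflectance_grid() -> WavelengthGrid:
    """Reflectance is sampled coarser than emission: 400-800 nm, 2 nm step."""
    return WavelengthGrid.from_range(400.0, 800.0, 2.0)


def generate_design(
    il_levels=DEFAULT_IL_LEVELS,
    hb_levels=DEFAULT_HB_LEVELS,
    ppix_levels=DEFAULT_PPIX_LEVELS,
    replicates: int = DEFAULT_REPLICATES,
) -> pd.DataFrame:
    """Full factorial composition grid with replicate index, in a fixed order."""
    if not (len(il_levels) and len(hb_levels) and len(ppix_levels) and replicates >= 1):
        raise ValueError("all level lists must be non-empty and replicates >= 1")
    rows = [
        (il, hb, ppix, rep)
        for il, hb, ppix, rep in itertools.product(
            il_levels, hb_levels, ppix_levels, range(replicates)
        )
    ]
    df = pd.DataFrame(rows, columns=["il_percent", "hb_mg_ml", "ppix_ug_ml", "replicate"])
    df.insert(0, "sample_id", [f"s{i:03d}" for i in range(len(df))])
    return df


def default_state_fraction(il: float, hb: float) -> float:
    """Fraction of PpIX emitting in the 620 nm (lipid-associated) state.

    Monotone surrogate for the lipid-driven blue shift: more intralipid
    pushes emission toward 620 nm, absorber slightly counteracts.
    """
    return float(np.clip(0.1 + 0.15 * il - 0.05 * hb, 0.0, 0.8))


def background_endmember(grid: WavelengthGrid, center: float = 520.0, width: float = 0.16) -> np.ndarray:
    """Broad log-normal-like autofluorescence hump (gelatin + intralipid)."""
    lam = grid.values
    return np.exp(-0.5 * (np.log(lam / center) / width) ** 2)


@dataclass
class ForwardModelParams:
    """Everything the forward model needs besides the composition row."""

    qe_620: float = 0.3          # quantum efficiency of the 620 state vs the 635 state
    alpha_true: float = -1.0     # exponent of the applied optical distortion
    counts_scale: float = 1e4    # expected peak counts of a 15 ug/ml 635-state sample
    bg_level: float = 0.12       # background peak fraction of counts_scale at 3% IL
    spike_level: float = 0.04    # 690 nm spike peak fraction of counts_scale at 3% IL
    primary_fwhm: float = 25.0
    secondary_amplitude: float = 0.2
    secondary_fwhm: float = 45.0
    spike_fwhm: float = 4.0
    state_fraction_rule: Callable[[float, float], float] = default_state_fraction
    seed: int = 0
    noise: bool = True

    def endmember_library(self, grid: WavelengthGrid) -> dict[str, np.ndarray]:
        """Unit-peak true endmember shapes on the emission grid."""
        t620 = PpixTemplate(620.0, self.primary_fwhm, 705.0,
                            self.secondary_amplitude, self.secondary_fwhm)
        t635 = PpixTemplate(635.0, self.primary_fwhm, 705.0,
                            self.secondary_amplitude, self.secondary_fwhm)
        return {
            "ppix620": t620.spectrum(grid),
            "ppix635": t635.spectrum(grid),
            "background": background_endmember(grid),
            "spike": make_noise_endmember(grid, 690.0, self.spike_fwhm),
        }


# haemoglobin-like absorption template (per mg/ml, 1/mm) and
# intralipid-like scattering (per % IL, 1/mm at 500 nm).  Amplitudes chosen
# so mu_a spans ~1-3.5 /mm at the Soret band and ~0.1-0.3 /mm in the red
# PpIX emission band over the 0.5-2 mg/ml design range, matching optical
# properties reported for brain-mimicking phantoms.
_HB_BANDS = ((415.0, 40.0, 2.4), (540.0, 35.0, 0.18), (576.0, 30.0, 0.16))
_HB_BASELINE = 0.12
_IL_MUSP_500 = 0.55
_IL_SCATTER = dict(f_ray=0.1, b_mie=0.9)


def _mu_a(hb: float, lam: np.ndarray) -> np.ndarray:
    out = np.full_like(lam, _HB_BASELINE, dtype=float)
    for center, fwhm, amp in _HB_BANDS:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    return hb * out


def _mu_s(il: float, lam: np.ndarray) -> np.ndarray:
    p = ScatteringFitParams(a_prime=_IL_MUSP_500 * max(il, 1e-12), lambda0=500.0, **_IL_SCATTER)
    return np.asarray(eval_rayleigh_mie(p, lam), float)


def simulate_reflectance(il: float, hb: float, grid: WavelengthGrid | None = None) -> ReflectanceRecord:
    """Albedo-like diffuse reflectance ``mu_s' / (mu_s' + mu_a)`` in (0, 1)."""
    if il < 0 or hb < 0:
        raise ValueError("concentrations must be non-negative")
    if il == 0 and hb == 0:
        raise ValueError("undefined medium: both optical agents are zero")
    grid = grid or reflectance_grid()
    lam = grid.values
    s = _mu_s(il, lam)
    a = _mu_a(hb, lam)
    return ReflectanceRecord(grid, s / (s + a), kind="diffuse")


@dataclass
class EmissionSample:
    clean: np.ndarray
    noisy: np.ndarray
    abundances: dict[str, float]


def _distortion(row, p: ForwardModelParams, grid: WavelengthGrid) -> np.ndarray:
    R_em = simulate_reflectance(row.il_percent, row.hb_mg_ml, grid)
    R_coarse = simulate_reflectance(row.il_percent, row.hb_mg_ml)
    r_ex = band_average_reflectance(R_coarse, DEFAULT_EX_BAND)
    return r_ex * R_em.values ** p.alpha_true


def simulate_emission(
    row,
    p: ForwardModelParams,
    grid: WavelengthGrid,
    rng: np.random.Generator | None = None,
) -> EmissionSample:
    """Simulate one sample's emission spectrum (clean and Poisson-noisy).

    ``row`` is a design row with il_percent / hb_mg_ml / ppix_ug_ml fields.
    Component amplitudes (pre-distortion, unit-peak shapes) are returned as
    ground truth.
    """
    lib = p.endmember_library(grid)
    f = p.state_fraction_rule(row.il_percent, row.hb_mg_ml)
    if not 0.0 <= f <= 1.0:
        raise ValueError("state fraction rule returned a value outside [0, 1]")
    ppix_max = max(DEFAULT_PPIX_LEVELS)
    a620 = p.counts_scale * (row.ppix_ug_ml / ppix_max) * f * p.qe_620
    a635 = p.counts_scale * (row.ppix_ug_ml / ppix_max) * (1.0 - f)
    a_bg = p.counts_scale * p.bg_level * (0.5 + 0.5 * row.il_percent / 3.0)
    a_spike = p.counts_scale * p.spike_level * (row.il_percent / 3.0)
    clean = (
        a620 * lib["ppix620"]
        + a635 * lib["ppix635"]
        + a_bg * lib["background"]
        + a_spike * lib["spike"]
    )
    clean = clean * _distortion(row, p, grid)
    if np.any(clean < 0):  # impossible by construction
        raise RuntimeError("negative clean intensity in forward model")
    if p.noise:
        if rng is None:
            rng = np.random.default_rng(p.seed)
        noisy = rng.poisson(clean).astype(float)
    else:
        noisy = clean.copy()
    return EmissionSample(
        clean=clean,
        noisy=noisy,
        abundances={"ppix620": a620, "ppix635": a635, "background": a_bg, "spike": a_spike},
    )


@dataclass
class PhantomDataset:
    """A simulated (or loaded) panel: spectra, reflectance and ground truth."""

    design: pd.DataFrame
    emission: SpectraMatrix
    reflectance: list[ReflectanceRecord]
    y: np.ndarray
    emission_clean: SpectraMatrix | None = None
    true_abundances: pd.DataFrame | None = None
    params: ForwardModelParams | None = None

    @property
    def n_samples(self) -> int:
        return self.emission.n_samples


def average_replicates(ds: "PhantomDataset") -> "PhantomDataset":
    """Collapse replicate measurements of each composition into their mean.

    Replicates share one ground-truth concentration; by default they are
    kept as separate samples and evaluation is per-measurement.  This
    helper returns the per-phantom aggregated view instead.
    """
    keys = ["il_percent", "hb_mg_ml", "ppix_ug_ml"]
    if not set(keys) <= set(ds.design.columns):
        raise ValueError("design lacks composition columns; cannot group replicates")
    groups = list(ds.design.groupby(keys, sort=False).groups.items())
    em_rows, refls, y, design_rows, ids = [], [], [], [], []
    for i, (key, idx) in enumerate(groups):
        rows = ds.design.index.get_indexer(idx)
        em_rows.append(ds.emission.values[rows].mean(axis=0))
        refls.append(ds.reflectance[rows[0]])
        y.append(float(ds.y[rows[0]]))
        sid = f"g{i:03d}"
        ids.append(sid)
        design_rows.append((sid, *key, 0))
    design = pd.DataFrame(design_rows,
                          columns=["sample_id", *keys, "replicate"])
    return PhantomDataset(
        design=design,
        emission=SpectraMatrix(ds.emission.grid, np.vstack(em_rows), ids),
        reflectance=refls,
        y=np.asarray(y),
        params=ds.params,
    )


def simulate_dataset(
    design: pd.DataFrame | None = None,
    params: ForwardModelParams | None = None,
    grid: WavelengthGrid | None = None,
) -> PhantomDataset:
    """Simulate the full panel; deterministic under a fixed params.seed."""
    if design is None:
        design = generate_design()
    if len(design) == 0:
        raise ValueError("empty design")
    params = params or ForwardModelParams()
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(params.seed)
    clean_rows, noisy_rows, refls, ab_rows = [], [], [], []
    for row in design.itertuples(index=False):
        sample = simulate_emission(row, params, grid, rng)
        clean_rows.append(sample.clean)
        noisy_rows.append(sample.noisy)
        refls.append(simulate_reflectance(row.il_percent, row.hb_mg_ml))
        ab_rows.append(sample.abundances)
    ids = [str(s) for s in design["sample_id"]]
    return PhantomDataset(
        design=design.reset_index(drop=True),
        emission=SpectraMatrix(grid, np.vstack(noisy_rows), ids),
        emission_clean=SpectraMatrix(grid, np.vstack(clean_rows), ids),
        reflectance=refls,
        y=design["ppix_ug_ml"].to_numpy(float),
        true_abundances=pd.DataFrame(ab_rows, index=ids),
        params=params,
    )


def write_dataset(ds: PhantomDataset, outdir) -> str:
    """Write the panel as delimited tables plus a manifest; returns the
    manifest path.  Output is byte-identical for a fixed seed."""
    os.makedirs(outdir, exist_ok=True)
    write_spectra(ds.emission, os.path.join(outdir, "emission.csv"))
    refl_grid = ds.reflectance[0].grid
    refl = SpectraMatrix(refl_grid, np.vstack([r.values for r in ds.reflectance]),
                         list(ds.emission.sample_ids))
    write_spectra(refl, os.path.join(outdir, "reflectance.csv"))
    y = pd.Series(ds.y, index=ds.emission.sample_ids)
    write_concentrations(y, os.path.join(outdir, "concentrations.csv"))
    ds.design.to_csv(os.path.join(outdir, "design.csv"), index=False)
    manifest = {
        "emission": "emission.csv",
        "reflectance": "reflectance.csv",
        "reflectance_kind": ds.reflectance[0].kind,
        "concentrations": "concentrations.csv",
        "design": "design.csv",
    }
    path = os.path.join(outdir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_dataset(manifest_path) -> PhantomDataset:
    """Load a panel written by :func:`write_dataset` (or hand-assembled)."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    def _p(key):
        return os.path.join(base, manifest[key])

    emission = load_spectra(_p("emission"))
    refl_sm = load_spectra(_p("reflectance"))
    kind = manifest.get("reflectance_kind", "diffuse")
    y = load_concentrations(_p("concentrations"))
    y = y.reindex(emission.sample_ids).to_numpy(float)
    if np.any(np.isnan(y)):
        raise ValueError("concentration table does not cover all samples")
    design = None
    if manifest.get("design"):
        design = pd.read_csv(_p("design"))
    else:
        design = pd.DataFrame({"sample_id": emission.sample_ids})
    return PhantomDataset(
        design=design,
        emission=emission,
        reflectance=reflectance_records(refl_sm, kind=kind),
        y=y,
    )
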