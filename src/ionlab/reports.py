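"""Run configuration, stage dispatch and report assembly.

A `RunConfig` names one analysis stage and its parameters; `run_stage`
validates it strictly (unknown keys are errors, referenced input paths
must exist), dispatches to the corresponding library function, writes any
configured outputs and returns a JSON-serialisable `Report` carrying the
results plus provenance (config hash, package version, seeds). Identical
config and seed therefore produce identical report hashes.

`assemble_discrimination_report` merges per-stage reports into the
combined isomer-assignment verdict: each contributing stage nominates a
winning candidate (best spectral similarity, CCS ordering, higher reaction
efficiency, proton-transfer exergonicity) and the merged verdict is the
majority nominee, flagged low-confidence when only one stage contributes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__ as _pkg_version
from . import action_spec, ccs_theory, formula_mass, kinetics, mobility, thermochem
from . import io as ionlab_io
from . import theory_spectra

__all__ = ["RunConfig", "Report", "run_stage", "assemble_discrimination_report",
           "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


# stage -> (required keys, optional keys)
_SCHEMAS: Dict[str, tuple] = {
    "mass": ({"formula", "charge"}, set()),
    "loss": ({"precursor_mz", "losses"}, set()),
    "irmpd": (
        {"scans_csv", "precursor_mz"},
        {"precursor_tol", "fragment_mzs", "fragment_tol", "log_base", "out_csv"},
    ),
    "assign": (
        {"spectrum_csv", "candidates"},
        {"scale", "fwhm", "lineshape", "method"},
    ),
    "mobility_calibrate": ({"calibrants_csv"}, {"edc", "gas_mass", "out_json"}),
    "mobility_ccs": (
        {"calibrants_csv", "td_ms", "mz", "z"},
        {"edc", "gas_mass"},
    ),
    "mobility_deconvolve": ({"mobilogram_csv"}, {"n_components"}),
    "ccs": ({"xyz"}, {"radii_yaml", "n_orientations", "n_samples", "seed"}),
    "kinetics": (
        {"trace_csv", "parent", "pressure_mbar"},
        {"temperature", "gauge_factor", "response_factor", "neutral"},
    ),
    "acidity": ({"neutral_g", "anion_g"}, {"unit", "proton_g_kjmol", "label",
                                           "temperature"}),
}

_PATH_KEYS = {"scans_csv", "calibrants_csv", "mobilogram_csv", "xyz", "trace_csv",
              "spectrum_csv", "radii_yaml"}


@dataclass
class RunConfig:
    stage: str
    params: Dict = field(default_factory=dict)
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if self.stage not in _SCHEMAS:
            raise ConfigError(
                f"unknown stage {self.stage!r}; valid: {sorted(_SCHEMAS)}"
            )
        required, optional = _SCHEMAS[self.stage]
        keys = set(self.params)
        missing = required - keys
        unknown = keys - required - optional
        if missing:
            raise ConfigError(f"stage {self.stage!r}: missing keys {sorted(missing)}")
        if unknown:
            raise ConfigError(f"stage {self.stage!r}: unknown keys {sorted(unknown)}")
        for k in keys & _PATH_KEYS:
            if not Path(self.params[k]).exists():
                raise ConfigError(f"stage {self.stage!r}: path {self.params[k]!r} "
                                  f"for {k!r} does not exist")

    def hash(self) -> str:
        blob = json.dumps(
            {"stage": self.stage, "params": self.params}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Report:
    stage: str
    results: Dict
    provenance: Dict = field(default_factory=dict)

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(
            {"stage": self.stage, "results": self.results, "provenance": self.provenance},
            indent=2,
            sort_keys=True,
            default=_jsonify,
        )
        if path:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "Report":
        d = json.loads(text)
        return cls(d["stage"], d["results"], d.get("provenance", {}))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _stage_mass(p: Dict) -> Dict:
    mz = formula_mass.ion_mz(p["formula"], int(p["charge"]))
    return {"formula": str(formula_mass.parse_formula(p["formula"])),
            "charge": int(p["charge"]), "mz": mz}


def _stage_loss(p: Dict) -> Dict:
    mz = formula_mass.neutral_loss_mz(float(p["precursor_mz"]), p["losses"])
    return {"fragment_mz": mz, "fragment_mz_nominal": formula_mass.format_one_decimal(mz)}


def _stage_irmpd(p: Dict) -> Dict:
    scans = ionlab_io.read_scans_csv(p["scans_csv"], float(p["precursor_mz"]))
    tol = float(p.get("precursor_tol", action_spec.DEFAULT_WINDOW_TOL))
    ftol = float(p.get("fragment_tol", action_spec.DEFAULT_WINDOW_TOL))
    frag_mzs = p.get("fragment_mzs")
    if frag_mzs is None:
        seen = sorted({mz for s in scans for mz in s.peaks[:, 0]})
        frag_mzs = [m for m in seen if abs(m - float(p["precursor_mz"])) > tol]
    spec = action_spec.build_action_spectrum(
        scans,
        action_spec.MzWindow(float(p["precursor_mz"]), tol),
        [action_spec.MzWindow(m, ftol) for m in frag_mzs],
        log_base=p.get("log_base", "e"),
    )
    out = {
        "energies_cm1": spec.energies.tolist(),
        "yields": spec.yields.tolist(),
        "provenance": spec.provenance,
    }
    if "out_csv" in p:
        import pandas as pd

        pd.DataFrame({"energy_cm1": spec.energies, "R": spec.yields}).to_csv(
            p["out_csv"], index=False
        )
        out["csv"] = p["out_csv"]
    return out


def _stage_assign(p: Dict) -> Dict:
    import pandas as pd

    df = pd.read_csv(p["spectrum_csv"])
    spec = action_spec.ActionSpectrum(df["energy_cm1"].to_numpy(), df["R"].to_numpy())
    broadened = []
    for cand in p["candidates"]:
        stick = ionlab_io.read_stick_csv(cand["csv"], cand["label"],
                                         cand.get("delta_g_kjmol"))
        broadened.append(
            theory_spectra.scale_and_broaden(
                stick,
                scale=float(p.get("scale", theory_spectra.DEFAULT_SCALE)),
                fwhm=float(p.get("fwhm", theory_spectra.DEFAULT_FWHM)),
                lineshape=p.get("lineshape", "gaussian"),
                grid_range=(spec.energies[0], spec.energies[-1]),
            )
        )
    ranked = theory_spectra.match_and_rank(spec, broadened,
                                           method=p.get("method", "cosine"))
    return {"ranking": [{"label": l, "score": s} for l, s in ranked],
            "winner": ranked[0][0]}


def _stage_mobility_calibrate(p: Dict) -> Dict:
    points = ionlab_io.read_calibrants_csv(p["calibrants_csv"])
    cal = mobility.fit_tw_calibration(
        points, edc=float(p.get("edc", mobility.DEFAULT_EDC)),
        gas_mass=float(p.get("gas_mass", 28.006)),
    )
    out = {"A": cal.A, "B": cal.B, "edc": cal.edc, "gas_mass": cal.gas_mass,
           "r_squared": cal.r_squared}
    if "out_json" in p:
        Path(p["out_json"]).write_text(json.dumps(out, indent=2))
    return out


def _stage_mobility_ccs(p: Dict) -> Dict:
    points = ionlab_io.read_calibrants_csv(p["calibrants_csv"])
    cal = mobility.fit_tw_calibration(
        points, edc=float(p.get("edc", mobility.DEFAULT_EDC)),
        gas_mass=float(p.get("gas_mass", 28.006)),
    )
    ccs = mobility.drift_to_ccs(float(p["td_ms"]), float(p["mz"]), int(p["z"]), cal)
    return {"ccs_A2": ccs, "A": cal.A, "B": cal.B, "r_squared": cal.r_squared}


def _stage_mobility_deconvolve(p: Dict) -> Dict:
    mob = ionlab_io.read_mobilogram_csv(p["mobilogram_csv"])
    return mobility.deconvolve_mobilogram(mob, int(p.get("n_components", 1)))


def _stage_ccs(p: Dict) -> Dict:
    geom = ccs_theory.read_xyz(p["xyz"])
    radii = (ccs_theory.load_radii(p["radii_yaml"]) if "radii_yaml" in p
             else ccs_theory.default_radii())
    res = ccs_theory.pa_ccs(
        geom, radii,
        n_orientations=int(p.get("n_orientations", 300)),
        n_samples=int(p.get("n_samples", 4000)),
        seed=p.get("seed"),
    )
    return {"label": geom.label, "ccs_A2": res.ccs_A2, "stderr_A2": res.stderr_A2,
            "n_orientations": res.n_orientations, "n_samples": res.n_samples,
            "seed": res.seed}


def _stage_kinetics(p: Dict) -> Dict:
    trace = ionlab_io.read_trace_csv(p["trace_csv"], parent=p["parent"])
    kprime, stderr = kinetics.fit_pseudo_first_order(trace)
    cal = kinetics.GaugeCalibration(
        factor=float(p.get("gauge_factor", 1.0)),
        response=float(p.get("response_factor", 1.0)),
    )
    temp = float(p.get("temperature", 300.0))
    n = kinetics.number_density(float(p["pressure_mbar"]), cal, temp)
    rates = kinetics.channel_rates(kprime, n, trace.product_abundances(), stderr)
    out = {
        "kprime_s": rates.kprime_s, "kprime_stderr": rates.kprime_stderr,
        "n_cm3": rates.n_cm3, "k_exp": rates.k_exp, "channels": rates.channels,
        "k_exp_uncertainty": rates.k_exp_uncertainty,
    }
    neutral = p.get("neutral")
    if neutral:
        ion_mass = float(neutral["ion_mass_da"])
        k_ado = kinetics.collision_rate_ado(
            ion_mass, float(neutral["mass_da"]), float(neutral["alpha_A3"]),
            float(neutral["dipole_D"]), temp,
        )
        out["k_ado"] = k_ado
        out["efficiency_pct"] = kinetics.efficiency(rates.k_exp, k_ado)
        out["channel_efficiency_pct"] = {
            name: kinetics.efficiency(k, k_ado) for name, k in rates.channels.items()
        }
    return out


def _stage_acidity(p: Dict) -> Dict:
    unit = p.get("unit", "hartree")
    temp = float(p.get("temperature", 298.15))
    label = p.get("label", "species")
    res = thermochem.gas_phase_acidity(
        thermochem.SpeciesThermo(label, float(p["neutral_g"]), unit, temp),
        thermochem.SpeciesThermo(label + "_anion", float(p["anion_g"]), unit, temp),
        proton_g_kjmol=float(p.get("proton_g_kjmol", thermochem.PROTON_G_KJMOL)),
    )
    return {"label": res.label, "dg_acid_kjmol": res.dg_acid_kjmol,
            "proton_g_kjmol": res.proton_g_kjmol, "temperature": res.temperature}


_DISPATCH = {
    "mass": _stage_mass,
    "loss": _stage_loss,
    "irmpd": _stage_irmpd,
    "assign": _stage_assign,
    "mobility_calibrate": _stage_mobility_calibrate,
    "mobility_ccs": _stage_mobility_ccs,
    "mobility_deconvolve": _stage_mobility_deconvolve,
    "ccs": _stage_ccs,
    "kinetics": _stage_kinetics,
    "acidity": _stage_acidity,
}


def run_stage(config: RunConfig) -> Report:
    """Validate a config, run its stage, and return a provenance-stamped report."""
    config.validate()
    results = _DISPATCH[config.stage](config.params)
    report = Report(
        stage=config.stage,
        results=results,
        provenance={
            "config_hash": config.hash(),
            "package_version": _pkg_version,
            "seed": config.params.get("seed"),
        },
    )
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / f"{config.stage}_report.json")
    return report


def assemble_discrimination_report(
    spectral: Optional[Dict] = None,
    mobility_cmp: Optional[Dict] = None,
    kinetics_cmp: Optional[Dict] = None,
    acidity_cmp: Optional[Dict] = None,
) -> Report:
    """Merge per-stage candidate comparisons into an assignment verdict.

    Each input is a dict with a `candidates` map (label -> stage-specific
    fields) and a `winner` label. Candidate label sets must agree across
    the stages provided; the verdict is the majority winner, marked
    low-confidence when only one stage contributes and conflicted when
    there is no majority.
    """
    stages = {
        "spectral": spectral,
        "mobility": mobility_cmp,
        "kinetics": kinetics_cmp,
        "acidity": acidity_cmp,
    }
    present = {k: v for k, v in stages.items() if v is not None}
    if not present:
        raise ValueError("need at least one stage report")
    label_sets = {k: frozenset(v["candidates"]) for k, v in present.items()}
    if len(set(label_sets.values())) > 1:
        detail = {k: sorted(v) for k, v in label_sets.items()}
        raise ValueError(f"candidate labels disagree across stages: {detail}")
    labels = sorted(next(iter(label_sets.values())))

    table = {
        label: {k: v["candidates"][label] for k, v in present.items()}
        for label in labels
    }
    votes: Dict[str, int] = {}
    for v in present.values():
        w = v.get("winner")
        if w is not None:
            votes[w] = votes.get(w, 0) + 1
    if not votes:
        raise ValueError("no stage nominated a winner")
    best = max(votes, key=votes.get)
    n_votes = votes[best]
    if len(present) == 1:
        confidence = "low"
    elif n_votes > sum(votes.values()) / 2:
        confidence = "high" if n_votes == sum(votes.values()) else "medium"
    else:
        confidence = "conflicted"
    return Report(
        stage="discrimination",
        results={
            "verdict": best,
            "confidence": confidence,
            "votes": votes,
            "stages_used": sorted(present),
            "table": table,
        },
    )
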