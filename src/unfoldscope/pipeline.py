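"""End-to-end workflow: decays -> DAS -> transitions -> microenvironment -> FRET.

Stages run independently: a failed or unconfigured stage is marked as such in
the report and later stages still execute.  The report is deterministic for a
given config and seed (timings go to the log, never into the report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import cli_io, fret, structure, tcspc, transitions
from .errors import UnfoldscopeError

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("unfoldscope")


@dataclass
class RunConfig:
    """Flat configuration for a full analysis run (YAML on disk)."""

    # spectroscopy inputs
    decays_manifest: str | None = None
    irf: str | None = None
    spectrum: str | None = None
    transition_curves: dict[str, str] = field(default_factory=dict)
    # structural inputs
    pdb: str | None = None
    chain_roles: dict[str, str] = field(default_factory=dict)
    cterm_domain: str | None = None  # "CHAIN:start-end"
    fret_pairs: list[str] = field(default_factory=list)  # "A:194-A:250"
    # parameters
    n_components: int = 3
    neighbor_cutoff: float = 7.0
    quencher_cutoff: float = 5.5
    probe_radius: float = 1.4
    r0: float = fret.DEFAULT_R0
    dipole_angle_deg: float = fret.DEFAULT_LA_ANGLE_DEG
    temperature: float = transitions.DEFAULT_TEMPERATURE_K
    channel_width_ns: float = tcspc.DEFAULT_CHANNEL_WIDTH_NS
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        for cname, value in (
            ("neighbor_cutoff", self.neighbor_cutoff),
            ("quencher_cutoff", self.quencher_cutoff),
            ("probe_radius", self.probe_radius),
            ("r0", self.r0),
        ):
            if value <= 0:
                raise UnfoldscopeError(f"{cname} must be positive")

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def _parse_domain(text: str) -> structure.DomainDefinition:
    chain, _, interval = text.partition(":")
    start, _, end = interval.partition("-")
    return structure.DomainDefinition(chain=chain, start=int(start),
                                      end=int(end))


def _parse_residue(text: str) -> tuple[str, int]:
    chain, _, num = text.partition(":")
    return chain, int(num)


def _stage(report: dict, name: str, func) -> None:
    t0 = time.perf_counter()
    try:
        block = func()
        report["stages"][name] = {"status": "ok", "result": block}
    except FileNotFoundError as exc:
        report["stages"][name] = {"status": "failed", "error": str(exc)}
        log.error("stage %s failed: %s", name, exc)
    except UnfoldscopeError as exc:
        report["stages"][name] = {"status": "failed", "error": str(exc)}
        log.error("stage %s failed: %s", name, exc)
    log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and return the analysis report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log.info("pipeline start (seed %d)", config.seed)
    report: dict = {
        "provenance": {
            "package": "unfoldscope",
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "stages": {},
    }

    decay_fit = None

    if config.decays_manifest and config.irf:
        def stage_decays():
            nonlocal decay_fit
            traces = cli_io.load_decay_bundle(config.decays_manifest,
                                              config.channel_width_ns)
            irf_hist = cli_io.read_irf(config.irf, config.channel_width_ns)
            decay_fit = tcspc.global_fit(
                traces, irf_hist, n_components=config.n_components,
                seed=config.seed,
            )
            return cli_io.fit_report_dict(decay_fit)
        _stage(report, "decay_fit", stage_decays)
    else:
        report["stages"]["decay_fit"] = {"status": "skipped",
                                         "error": "no decay inputs configured"}

    if config.spectrum and decay_fit is not None and decay_fit.converged:
        def stage_das():
            spectrum = cli_io.read_spectrum(config.spectrum)
            frac, mean_frac = tcspc.spectral_fractions(decay_fit)
            das = tcspc.decay_associated_spectra(
                frac, decay_fit.model.wavelengths, spectrum
            )
            return {
                "wavelengths_nm": das.wavelengths.tolist(),
                "fractions": das.fractions.tolist(),
                "component_spectra": das.component_spectra.tolist(),
                "mean_fractions": das.mean_fractions.tolist(),
                "units": {"wavelengths_nm": "nm",
                          "component_spectra": "steady-state intensity units",
                          "fractions": "dimensionless"},
            }
        _stage(report, "das", stage_das)
    else:
        report["stages"]["das"] = {"status": "skipped",
                                   "error": "needs spectrum and converged fit"}

    def stage_transitions():
        blocks = {}
        for signal_name, path in config.transition_curves.items():
            curve = cli_io.read_transition_curve(path, signal_name)
            tfit = transitions.fit_transition(curve, n_transitions=2)
            thermo = (
                transitions.thermo_from_fit(tfit.params, config.temperature)
                if tfit.converged else None
            )
            block = {
                "signal_name": signal_name,
                "params": asdict(tfit.params),
                "stderr": tfit.stderr,
                "converged": tfit.converged,
                "thermo": (
                    {
                        "m_values_kJ_per_mol_M": list(thermo.m_values),
                        "dG_H2O_kJ_per_mol": list(thermo.dG_H2O),
                        "fractions": list(thermo.fractions),
                        "temperature_K": thermo.temperature,
                    }
                    if thermo else None
                ),
                "warnings": list(tfit.warnings),
                "units": {"c1": "M", "c2": "M", "k1": "M", "k2": "M",
                          "dG_H2O": "kJ/mol", "m": "kJ/mol/M",
                          "temperature": "K"},
            }
            cli_io.validate_report(block, "transition_fit")
            blocks[signal_name] = block
        if not blocks:
            raise UnfoldscopeError("no transition curves configured")
        return blocks

    if config.transition_curves:
        _stage(report, "transitions", stage_transitions)
    else:
        report["stages"]["transitions"] = {
            "status": "skipped", "error": "no transition curves configured"
        }

    if config.pdb:
        def stage_microenv():
            st = cli_io.read_pdb(config.pdb, chain_roles=config.chain_roles)
            domain = (_parse_domain(config.cterm_domain)
                      if config.cterm_domain else None)
            rep = structure.microenv_report(
                st, neighbor_cutoff=config.neighbor_cutoff,
                quencher_cutoff=config.quencher_cutoff,
                probe=config.probe_radius, domain=domain,
            )
            return {
                "table": rep.table.to_dict(orient="records"),
                "quenchers": {
                    f"{ch}:{num}": [asdict(c) for c in contacts]
                    for (ch, num), contacts in rep.quenchers.items()
                },
                "units": {"sasa_abs_A2": "A^2", "sasa_rel_pct": "%",
                          "n_sec_pct": "%", "distances": "A"},
            }
        _stage(report, "microenv", stage_microenv)

        def stage_fret():
            st = cli_io.read_pdb(config.pdb, chain_roles=config.chain_roles)
            blocks = []
            pairs = config.fret_pairs
            if not pairs:
                trps = structure.find_tryptophans(st)
                pairs = [
                    f"{a[0]}:{a[1]}-{b[0]}:{b[1]}"
                    for i, a in enumerate(trps) for b in trps[i + 1:]
                ]
            for pair_text in pairs:
                donor_text, _, acceptor_text = pair_text.partition("-")
                donor = _parse_residue(donor_text)
                acceptor = _parse_residue(acceptor_text)
                fp = fret.fret_pair(st, donor, acceptor, R0=config.r0,
                                    angle_deg=config.dipole_angle_deg)
                k2_lo, k2_hi = fret.kappa2_sensitivity(
                    st, donor, acceptor, angle_deg=config.dipole_angle_deg
                )
                block = {
                    "donor": donor_text, "acceptor": acceptor_text,
                    "R_A": fp.R, "kappa2": fp.kappa2,
                    "efficiency": fp.efficiency, "R0_A": fp.R0,
                    "dipole_angle_deg": config.dipole_angle_deg,
                    "kappa2_range": [k2_lo, k2_hi],
                    "units": {"R_A": "A", "R0_A": "A",
                              "efficiency": "fraction",
                              "kappa2": "dimensionless"},
                }
                cli_io.validate_report(block, "fret")
                blocks.append(block)
            return blocks
        _stage(report, "fret", stage_fret)
    else:
        for name in ("microenv", "fret"):
            report["stages"][name] = {"status": "skipped",
                                      "error": "no structure input configured"}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cli_io.dump_json(report, outdir / "analysis_report.json")
    log.info("pipeline done")
    return report
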