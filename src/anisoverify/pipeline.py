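"""End-to-end verification workflow: one structured report per candidate set.

Each enabled evidence stage — correlation-network consistency, anisotropic
(RDC/RCSA) Q-factor fitting, chemical-shift agreement — scores every
candidate independently; the report presents per-criterion ranks side by
side without combining them into a composite score, since the criteria are
independent converging lines of evidence and any cross-criterion weighting
would be arbitrary.  The run is "unambiguous" (exit code 0 from the CLI)
only when a single candidate is best-or-tied-best on every enabled
criterion.

Config (YAML)::

    seed: 7                        # recorded in provenance
    candidates:
      - name: proposed
        structure: proposed.sdf
        labels: labels.csv
    stages:
      consistency:
        correlations: corr.csv     # experiment, from, to
        rules: rules.yaml          # optional
        noe_cutoff_A: 5.0
      aniso:
        rdc: rdc.csv
        rcsa: rcsa.csv
        shielding:                 # one CSV, or mapping candidate -> CSV
          proposed: shielding.csv
        weighting: by_sigma
      shifts:
        exp: exp_shifts.csv        # position, shift_ppm
        calc:
          proposed: calc_shifts.csv
        statistic: corrected_rmsd
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .graph import (MoleculeGraph, classify_correlations, load_rules,
                    noe_distance_check, read_structure)
from .saupe import (SaupeModel, read_rcsa_csv, read_rdc_csv, read_shielding_csv)
from .shifts import compare_shift_sets
from .tables import Experiment, read_correlations


class ConfigError(ValueError):
    """Invalid or incomplete verification config."""


@dataclass
class VerificationReport:
    candidates: list[str]
    criteria: dict[str, dict[str, dict]]     # stage -> candidate -> metrics
    ranks: dict[str, dict[str, int]]         # stage -> candidate -> rank (1 = best)
    status: str                              # unambiguous | ambiguous
    best: str | None
    provenance: dict

    def to_dict(self) -> dict:
        return {"candidates": self.candidates, "criteria": self.criteria,
                "ranks": self.ranks, "status": self.status, "best": self.best,
                "provenance": self.provenance}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    def summary(self) -> str:
        lines = ["Structure verification report",
                 "=============================",
                 f"candidates: {', '.join(self.candidates)}", ""]
        for stage, ranks in self.ranks.items():
            lines.append(f"[{stage}]")
            for name in sorted(ranks, key=ranks.get):
                metrics = self.criteria[stage][name]
                detail = ", ".join(f"{k}={v:.4g}" if isinstance(v, float)
                                   else f"{k}={v}" for k, v in metrics.items())
                lines.append(f"  #{ranks[name]} {name}: {detail}")
            lines.append("")
        lines.append(f"status: {self.status}"
                     + (f" (best: {self.best})" if self.best else ""))
        return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _rank(scores: dict[str, tuple]) -> dict[str, int]:
    """Competition ranks, ties sharing the better rank."""
    ordered = sorted(scores, key=lambda n: (scores[n], ))
    ranks: dict[str, int] = {}
    for i, name in enumerate(ordered):
        if i and scores[name] == scores[ordered[i - 1]]:
            ranks[name] = ranks[ordered[i - 1]]
        else:
            ranks[name] = i + 1
    return ranks


def run_verification(config: str | Path | dict,
                     verbose: bool = False) -> VerificationReport:
    """Run every enabled stage of a verification config and aggregate ranks."""
    inputs: dict[str, str] = {}
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        cfg = yaml.safe_load(cfg_path.read_text())
        base = cfg_path.parent
    else:
        cfg, base = dict(config), Path(".")

    def resolve(p) -> Path:
        path = Path(p)
        path = path if path.is_absolute() else base / path
        inputs[str(p)] = _sha256(path)
        return path

    cand_cfg = cfg.get("candidates") or []
    if not cand_cfg:
        raise ConfigError("config names no candidates")
    stages_cfg = cfg.get("stages") or {}
    if not stages_cfg:
        raise ConfigError("config enables no stages")

    candidates: list[tuple[str, MoleculeGraph]] = []
    for c in cand_cfg:
        g = read_structure(resolve(c["structure"]),
                           label_map=resolve(c["labels"]) if c.get("labels") else None,
                           name=c.get("name"))
        candidates.append((c.get("name", g.name), g))
    names = [n for n, _ in candidates]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate candidate names")

    criteria: dict[str, dict[str, dict]] = {}
    ranks: dict[str, dict[str, int]] = {}

    if "consistency" in stages_cfg:
        sc = stages_cfg["consistency"]
        rules = load_rules(resolve(sc["rules"])) if sc.get("rules") else None
        cutoff = float(sc.get("noe_cutoff_A", 5.0))
        corr_sets = read_correlations(resolve(sc["correlations"]))
        stage: dict[str, dict] = {}
        scores: dict[str, tuple] = {}
        for name, g in candidates:
            totals = {"expected": 0, "tolerated": 0, "violation": 0,
                      "unreachable": 0}
            for cs in corr_sets:
                if cs.experiment in (Experiment.NOESY, Experiment.ROESY):
                    rep = noe_distance_check(g, cs, cutoff_A=cutoff)
                else:
                    rep = classify_correlations(g, cs, rules)
                for k, v in rep.counts.items():
                    totals[k] += v
            stage[name] = totals
            scores[name] = (totals["violation"], totals["unreachable"],
                            totals["tolerated"])
        criteria["consistency"] = stage
        ranks["consistency"] = _rank(scores)

    if "aniso" in stages_cfg:
        sa = stages_cfg["aniso"]
        rdc = read_rdc_csv(resolve(sa["rdc"])) if sa.get("rdc") else []
        sh_cfg = sa.get("shielding")
        rcsa_path = resolve(sa["rcsa"]) if sa.get("rcsa") else None
        weighting = sa.get("weighting", "by_sigma")
        stage, scores = {}, {}
        for name, g in candidates:
            rcsa = []
            if rcsa_path is not None:
                if isinstance(sh_cfg, dict):
                    if name not in sh_cfg:
                        raise ConfigError(f"no shielding CSV for candidate {name!r}")
                    sh = read_shielding_csv(resolve(sh_cfg[name]))
                else:
                    sh = read_shielding_csv(resolve(sh_cfg)) if sh_cfg else None
                rcsa = read_rcsa_csv(rcsa_path, sh)
            res = SaupeModel(g, rdc, rcsa, weighting=weighting).fit()
            stage[name] = {"q_total": res.q_total,
                           "q_rdc": res.q_rdc, "q_rcsa": res.q_rcsa,
                           "n_rdc": res.n_rdc, "n_rcsa": res.n_rcsa,
                           "condition_number": res.condition_number}
            scores[name] = (round(res.q_total, 12),)
        criteria["aniso"] = stage
        ranks["aniso"] = _rank(scores)

    if "shifts" in stages_cfg:
        ss = stages_cfg["shifts"]
        statistic = ss.get("statistic", "corrected_rmsd")
        exp_df = pd.read_csv(resolve(ss["exp"]), dtype={"position": str})
        exp = dict(zip(exp_df["position"], exp_df["shift_ppm"].astype(float)))
        calc_cfg = ss.get("calc") or {}
        stage, scores = {}, {}
        for name, _ in candidates:
            if name not in calc_cfg:
                raise ConfigError(f"no computed shifts for candidate {name!r}")
            cdf = pd.read_csv(resolve(calc_cfg[name]), dtype={"position": str})
            calc = dict(zip(cdf["position"], cdf["shift_ppm"].astype(float)))
            comp = compare_shift_sets(exp, calc, rescale=True)
            stage[name] = {"n": comp.n, "mae": comp.mae, "rmsd": comp.rmsd,
                           "corrected_rmsd": comp.corrected_rmsd,
                           "max_abs_dev": comp.max_abs_dev}
            scores[name] = (round(comp.statistic(statistic), 12),)
        criteria["shifts"] = stage
        ranks["shifts"] = _rank(scores)

    if not criteria:
        raise ConfigError("no recognized stages enabled")

    leaders = set(names)
    for stage_ranks in ranks.values():
        leaders &= {n for n, r in stage_ranks.items() if r == 1}
    if len(leaders) == 1:
        status, best = "unambiguous", leaders.pop()
    else:
        status, best = "ambiguous", None

    provenance = {"version": __version__, "seed": cfg.get("seed"),
                  "inputs_sha256": inputs, "config": cfg}
    return VerificationReport(names, criteria, ranks, status, best, provenance)
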