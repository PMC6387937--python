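"""Library characterization: rule-of-three compliance, polarity, shape and
halogen-stratified sigma-hole summaries.

The rule of three (fragment-likeness) counts violations of MW <= 300 Da,
clogP <= 3, <= 3 H-bond donors, <= 3 acceptors and <= 3 rotatable bonds;
TPSA is profiled against the 60 and 90 A^2 guidelines.  Shape is profiled
as mean Fsp3 plus the (NPR1, NPR2) shape-triangle points of one embedded
conformer per molecule.  V_max distributions are summarized per halogen
element as quartiles against the halobenzene reference lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .chemio import MoleculeRecord
from .descriptors import DescriptorSet, molecular_descriptors, pmi_shape
from .featuretree import enumerate_configurations

#: Halobenzene V_max reference baselines (au) drawn as guide lines.
VMAX_REFERENCES = {"Cl": 0.008, "Br": 0.016, "I": 0.025}


@dataclass(frozen=True)
class Ro3Report:
    n: int
    mw_gt_300: int
    clogp_gt_3: int
    hbd_gt_3: int
    hba_gt_3: int
    rb_gt_3: int
    tpsa_gt_60: int
    tpsa_gt_90: int
    fully_compliant: int  # no rule-of-three violation

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def ro3_report(
    records: Sequence[MoleculeRecord],
    descriptors: Mapping[str, DescriptorSet] | None = None,
    hbond_rule: str = "no_count",
) -> Ro3Report:
    """Independent per-rule violation counts plus the fully compliant count."""
    descs = descriptors or {
        rec.id: molecular_descriptors(rec, hbond_rule=hbond_rule) for rec in records
    }
    counts = dict.fromkeys(("mw", "clogp", "hbd", "hba", "rb", "t60", "t90"), 0)
    compliant = 0
    for rec in records:
        d = descs[rec.id]
        violated = False
        for key, bad in (
            ("mw", d.mw > 300),
            ("clogp", d.clogp > 3),
            ("hbd", d.hbd > 3),
            ("hba", d.hba > 3),
            ("rb", d.rotatable_bonds > 3),
        ):
            if bad:
                counts[key] += 1
                violated = True
        counts["t60"] += d.tpsa > 60
        counts["t90"] += d.tpsa > 90
        compliant += not violated
    return Ro3Report(
        n=len(records),
        mw_gt_300=counts["mw"],
        clogp_gt_3=counts["clogp"],
        hbd_gt_3=counts["hbd"],
        hba_gt_3=counts["hba"],
        rb_gt_3=counts["rb"],
        tpsa_gt_60=counts["t60"],
        tpsa_gt_90=counts["t90"],
        fully_compliant=compliant,
    )


@dataclass(frozen=True)
class ShapeProfile:
    fsp3_mean: float
    shape_points: tuple[tuple[str, float, float], ...]  # (id, npr1, npr2)
    embedding_failures: tuple[str, ...]


def shape_profile(
    records: Sequence[MoleculeRecord], conformer_seed: int = 2019
) -> ShapeProfile:
    """Mean Fsp3 over the library plus one shape-triangle point per
    embeddable molecule; embedding failures are reported, not dropped
    silently."""
    fsp3 = [molecular_descriptors(rec).fsp3 for rec in records]
    points = []
    failures = []
    for rec in records:
        shape = pmi_shape(rec, conformer_seed)
        if shape is None:
            failures.append(rec.id)
        else:
            points.append((rec.id, shape.npr1, shape.npr2))
    return ShapeProfile(
        fsp3_mean=float(np.mean(fsp3)) if fsp3 else 0.0,
        shape_points=tuple(points),
        embedding_failures=tuple(failures),
    )


@dataclass(frozen=True)
class VmaxSummary:
    per_element: Mapping[str, tuple[float, float, float, float, float]]  # min,Q1,med,Q3,max
    references: Mapping[str, float] = field(default_factory=lambda: dict(VMAX_REFERENCES))
    surface: str = ""


def vmax_profile(
    records: Sequence[MoleculeRecord],
    vmax_provider: Callable,
) -> VmaxSummary:
    """Per-element (Cl/Br/I) five-number summaries of configuration V_max.

    Quartiles use linear interpolation (type 7).  All values must share
    one isodensity surface tag; mixing tags is an error.
    """
    by_element: dict[str, list[float]] = {}
    surfaces = set()
    for rec in records:
        for cfg in enumerate_configurations(rec):
            vrec = vmax_provider(rec, cfg)
            surfaces.add(vrec.surface)
            by_element.setdefault(cfg.element, []).append(vrec.value)
    if len(surfaces) > 1:
        raise ValueError(f"mixed V_max surface tags in one profile: {sorted(surfaces)}")
    summary = {
        el: tuple(float(q) for q in np.percentile(vals, [0, 25, 50, 75, 100]))
        for el, vals in sorted(by_element.items())
    }
    return VmaxSummary(per_element=summary, surface=next(iter(surfaces), ""))


@dataclass(frozen=True)
class LibraryProfile:
    n: int
    ro3: Ro3Report
    shape: ShapeProfile
    vmax: VmaxSummary | None

    def to_json_payload(self) -> dict:
        payload = {
            "n": self.n,
            "ro3": self.ro3.as_dict(),
            "fsp3_mean": self.shape.fsp3_mean,
            "shape_points": [[i, round(a, 6), round(b, 6)] for i, a, b in self.shape.shape_points],
            "embedding_failures": list(self.shape.embedding_failures),
        }
        if self.vmax is not None:
            payload["vmax"] = {
                "surface": self.vmax.surface,
                "per_element": {k: list(v) for k, v in self.vmax.per_element.items()},
                "references": dict(self.vmax.references),
            }
        return payload

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_payload(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def profile_library(
    records: Sequence[MoleculeRecord],
    conformer_seed: int = 2019,
    vmax_provider: Callable | None = None,
    hbond_rule: str = "no_count",
) -> LibraryProfile:
    """Full characterization of a fragment library."""
    return LibraryProfile(
        n=len(records),
        ro3=ro3_report(records, hbond_rule=hbond_rule),
        shape=shape_profile(records, conformer_seed),
        vmax=vmax_profile(records, vmax_provider) if vmax_provider is not None else None,
    )


def characterize_library(
    records: Sequence[MoleculeRecord],
    conformer_seed: int = 2019,
    hbond_rule: str = "no_count",
) -> dict:
    """Headline characterization numbers of a library, as printed in
    fragment-library reports: size, rule-of-three violation counts, TPSA
    guideline counts and mean Fsp3 (2 d.p.)."""
    ro3 = ro3_report(records, hbond_rule=hbond_rule)
    fsp3 = float(np.mean([molecular_descriptors(r).fsp3 for r in records])) if records else 0.0
    return {
        "n": ro3.n,
        "mw_violations": ro3.mw_gt_300,
        "hba_gt_3": ro3.hba_gt_3,
        "rb_gt_3": ro3.rb_gt_3,
        "tpsa_gt_60": ro3.tpsa_gt_60,
        "tpsa_gt_90": ro3.tpsa_gt_90,
        "fsp3_mean": round(fsp3, 2),
    }


def plot_profile(profile: LibraryProfile, outdir: str | Path) -> list[Path]:
    """Optional matplotlib plots: PMI shape triangle and per-element V_max
    boxes.  Returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if profile.shape.shape_points:
        fig, ax = plt.subplots(figsize=(5, 5))
        xs = [p[1] for p in profile.shape.shape_points]
        ys = [p[2] for p in profile.shape.shape_points]
        ax.plot([0, 0.5, 1, 0], [1, 0.5, 1, 1], "k--", lw=0.8)
        ax.scatter(xs, ys, s=12, alpha=0.6)
        ax.set_xlabel("NPR1 (I1/I3)")
        ax.set_ylabel("NPR2 (I2/I3)")
        ax.set_title("Shape triangle (rod / disc / sphere)")
        path = outdir / "pmi_triangle.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if profile.vmax is not None and profile.vmax.per_element:
        fig, ax = plt.subplots(figsize=(5, 4))
        elements = list(profile.vmax.per_element)
        data = [profile.vmax.per_element[e] for e in elements]
        ax.boxplot(
            [[d[0], d[1], d[2], d[3], d[4]] for d in data], tick_labels=elements
        )
        for i, e in enumerate(elements, start=1):
            ref = profile.vmax.references.get(e)
            if ref is not None:
                ax.hlines(ref, i - 0.3, i + 0.3, linestyles="dashed")
        ax.set_ylabel("V_max (au)")
        ax.set_title(f"Sigma-hole magnitude by halogen (surface {profile.vmax.surface} au)")
        path = outdir / "vmax_by_element.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    return written
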