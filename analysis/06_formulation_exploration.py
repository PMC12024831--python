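"""Propagate the four solid-dispersion release profiles through the
absorption model and compare them with the IR tablet.

The dispersed profiles drive release wherever the formulation resides in
the GI tract; precipitation is disabled for the dispersions (the polymer
carriers act as precipitation inhibitors).  Release beyond the 330-min
test continues at the terminal-stage rate (an eroding matrix does not
stop releasing when the in vitro test ends).

Findings, mirroring the study: fraction absorbed orders as
C5 > P9 > C9 > P5 > IR; the slow-release P9 absorbs mostly in the
cecum + ascending colon (> 50% of the absorbed dose) and shows the
lowest liver concentration peak; AUC improvements over the IR tablet
exceed 100% for the best dispersions.

Writes results/formulation_comparison.csv and
results/regional_absorption.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import clopbbm as cb
from clopbbm import datasets


def main(out_dir: Path) -> None:
    drug = datasets.clopidogrel_drug_parameters()
    disp = datasets.clopidogrel_disposition_parameters()

    results = {"IR": cb.simulate_oral(
        drug, disp, None,
        cb.ReleaseSource.from_psd(drug.d50_um, drug.d90_um, n_bins=10),
        cb.DoseEvent(route="po", dose=75.0), t_end=24.0)}
    for name, spec in cb.formulation_presets().items():
        source = cb.ReleaseSource.from_profile(cb.generate_profile(spec))
        results[name] = cb.simulate_oral(
            drug, disp, None, source, cb.DoseEvent(route="po", dose=75.0),
            t_end=24.0, precipitation=False)

    ir_auc = results["IR"].metrics.AUC_0_inf
    rows, regional_rows = [], []
    for name, res in results.items():
        m = res.metrics
        rows.append({
            "formulation": name,
            "Fa_pct": round(res.Fa, 3), "Fb_pct": round(res.Fb, 3),
            "Cmax_ng_mL": round(m.Cmax, 2), "tmax_h": round(m.tmax, 2),
            "AUC_0_inf": round(m.AUC_0_inf, 2),
            "Cmax_liver_ng_mL": round(float(res.liver_conc.max()), 1),
            "AUC_improvement_vs_IR_pct":
                round(cb.percent_improvement(m.AUC_0_inf, ir_auc), 2),
        })
        for comp, share in res.regional_absorbed.items():
            regional_rows.append({"formulation": name, "compartment": comp,
                                  "percent_of_absorbed": round(share, 2)})

    df = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "formulation_comparison.csv", index=False)
    pd.DataFrame(regional_rows).to_csv(
        out_dir / "regional_absorption.csv", index=False)
    print(df.to_string(index=False))

    order = df.sort_values("Fa_pct", ascending=False).formulation.tolist()
    print("\nFa rank:", " > ".join(order))
    p9 = results["P9"].regional_absorbed
    print(f"P9 cecum+colon share: {p9['cecum'] + p9['asc_colon']:.1f}% of absorbed")
    print(f"wrote {out_dir}/formulation_comparison.csv and regional_absorption.csv")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--out-dir", type=Path, default=Path("results"))
    main(p.parse_args().out_dir)
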