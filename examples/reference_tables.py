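"""Recompute the headline statistics from the bundled MutS-DNA reference tables.

Each number is a property of the published ensemble averages themselves:
how well force-field pair energies track the QM ones, how the
backbone/side-chain blocks regress, how per-bond budgets close, and how far
charge transfer pulls residue charges off their formal integers.
"""

from pienet import datasets
from pienet.qm import charge_deviation, per_type_functional_charge
from pienet.report import regress

pairs = datasets.load_pair_energies().set_index("pair")
cov = {p: "covalent pair" for p in pairs.index[pairs.is_covalent]}

fit = regress(pairs["mm_mean"], pairs["pa_solute_mean"], exclude=cov)
print(f"MM vs QM solute PIEs (residues):   R^2 = {fit.r_squared:.3f}  (n={fit.n})")

fit = regress(pairs["pa_solution_frag_mean"], pairs["fmo_solution_frag_mean"],
              exclude=cov)
print(f"Fractional vs integer charges:     R^2 = {fit.r_squared:.3f}  (n={fit.n})")

sub = datasets.load_subunit_contributions().set_index("pair")
cov = {p: "covalent pair" for p in sub.index[sub.is_covalent]}
fit = regress(sub["mm_bb"], sub["qm_solute_bb"], exclude=cov)
print(f"Backbone-backbone, QM on MM:       slope = {fit.slope:.3f}, "
      f"R^2 = {fit.r_squared:.3f}")
fit = regress(sub["mm_ff"], sub["qm_solute_ff"], exclude=cov)
print(f"Functional-functional, QM on MM:   R^2 = {fit.r_squared:.3f}  (n={fit.n}, "
      "glycine pair dropped)")

groups = datasets.load_group_energies()
for pair in ("A13:T18", "C7:G24", "G8:T23"):
    grp = groups[groups.pair == pair]
    named = grp[grp.bond != "total"]["mean"].sum()
    total = grp[grp.bond == "total"]["mean"].iloc[0]
    print(f"{pair}: named bonds + rest = {named:.1f}, printed total = {total}")

charges = datasets.load_residue_charges()
charged = charges[charges.formal_charge != 0]
dev = {
    r["label"]: charge_deviation({"total_charge": r["qm_res_total_mean"],
                                  "formal_charge": r["formal_charge"]})
    for _, r in charged.iterrows()
}
worst = max(dev, key=dev.get)
print(f"Largest charge-transfer deviation: {worst} at {dev[worst]:.1f}% of formal")
g_mean = per_type_functional_charge(charges, "G", value_col="qm_res_funct_mean")
print(f"Mean guanine base charge:          {g_mean:.4f} e (rounds to {g_mean:.2f})")
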