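# lapkit

A toolkit for **standardized laboratory-automation protocols** in
synthetic biology.  Liquid-handling robots make cloning, screening and
culture workflows scalable, but the scripts that drive them are usually
one-off and lab-specific.  lapkit implements a standard around three
ideas:

1. **A naming grammar** for protocols —
   `LAP-<Description>-<Platform>-<major.minor.patch>` — and a fixed
   three-section script structure (*Classes*, *Functions*, *Body*), so
   protocols are identifiable, versioned and structurally uniform.
2. **Customizable Variable Files (CVFs)** — the user edits a spreadsheet
   (or JSON/XML) of named variables, never the code.  lapkit parses four
   dialects, type-checks every variable against a per-protocol schema
   and reports *all* problems at once (missing tip racks, volumes that
   would overfill a well, malformed numbers, unknown labware).
3. **A virtual liquid-handling robot** that executes computed plans with
   strict accounting: volume conservation, tip logistics, overfill and
   dead-volume protection, and liquid-level (z) tracking for conical
   tubes.

It is aimed at wet-lab automation developers who want to validate a
protocol — deck layout, reagent totals, pipetting feasibility — before
any robot time is booked, and at end users who only ever touch the
variable file.

## The core computations

**Movement-optimal pipette choice.** A pipette with working range
[*v*<sub>min</sub>, *v*<sub>max</sub>] moves a volume *V* in
*k* = ⌈*V*/*v*<sub>max</sub>⌉ aspirate–dispense cycles, feasible iff
*k*·*v*<sub>min</sub> ≤ *V*.  `give_me_optimal_pipette` minimizes *k*
over the mounted pipettes and returns a valid chunking (ties prefer the
less oversized pipette, then the right mount).

**Liquid-level tracking.** A 15 mL conical tube is modeled as an
inverted cone (height *h*<sub>c</sub>, junction radius *r*) under a
cylinder, with 1 mm³ = 1 µL:

- cone: *V*(*h*) = (π/3)·(*r·h*/*h*<sub>c</sub>)²·*h*
- cylinder: *V*(*h*) = *V*(*h*<sub>c</sub>) + π*r*²·(*h* − *h*<sub>c</sub>)

Both branches invert in closed form, so before every aspiration the tip
descends to `height_from_volume(current volume) − 10 mm`, clamped to a
1 mm bottom clearance, and never below the 1 000 µL dead volume.

**Reagent planning.** Totals are `samples × per-sample volume × (1 +
excess fraction)`; tubes are allocated by ceiling division over the
usable volume per tube (90 % fill limit minus dead volume).

Shipped reference protocols: *cell inoculation in different media*,
*sample consolidation into a single 96-well plate*, *PCR master-mix
preparation with a temperature profile*, and *two-criteria counter
selection* (the screening step whose survivors feed consolidation and
then PCR — protocols compose into workflows by plan concatenation).

## Worked example

```bash
$ lap fixtures --seed 4 --out fixtures/
$ lap simulate consolidation --cvf fixtures/consolidation_valid.xlsx --out run/
OK: 152 steps executed, 3686 uL on deck
```

`run/` now contains `plan.json` (every aspirate/dispense with its
deck coordinates), `action_log.jsonl` (per-step pre/post state digests
and aspiration heights), `plate_96_well_slot4_map.csv` (which sample
ended in which well) and `metadata.yaml`.  The `3686 uL on deck` line
is the conservation check: for this seeded fixture (38 samples at
97 µL each) the deck holds 38 × 97 = 3 686 µL before and after the run —
liquid moved, none appeared or vanished.

```pycon
>>> from lapkit import give_me_optimal_pipette, make_pipette
>>> pair = [make_pipette("left", "p20_single"), make_pipette("right", "p300_single")]
>>> give_me_optimal_pipette(150, pair)
PipetteChoice(mount='right', movements=1, per_movement_volumes=(150,))
```

150 µL takes one movement with the 20–300 µL pipette instead of eight
with the 1–20 µL one.

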