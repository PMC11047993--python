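# synthchip

A desk-scale simulator of a high-throughput electrochemical
DNA-synthesis chip for DNA data storage: a DRAM-like integrated circuit
that addresses 10 million electrodes (3163 × 3163 at a 3.16 µm pitch,
10⁷/cm²) through only 145 pins, combined with a static-droplet-array
(SDA) microfluidic layer that traps one aqueous droplet over every
electrode so that the protons generated during electrochemical
deprotection stay confined to their own synthesis site.

The package is aimed at people studying or designing such platforms:
it lets you exercise the addressing logic and refresh timing, the
per-electrode storage-capacitor behaviour, the two-phase microfluidics
of droplet formation, and the phosphoramidite synthesis-cycle
orchestration that ties them together — all from Python or a small CLI.

## The models in brief

**Addressing.** One row decoder (12 bits → 3163 word lines) and 128
five-to-25 block decoders sharing a 5-bit offset bus select up to 128
units per 80 ns instance (one per enabled block, column
`b·25 + offset`). An arbitrary activation mask compiles into an exact
cover of `(row, offset)` instances; a full-array refresh is
`3163 × 25 = 79,075` instances = 6.3 ms.

**Electrode dynamics.** Each unit is a 1 pF capacitor behind an access
switch with on-resistance calibrated from the printed operating point
(3 V in 80 ns from a 5 V supply ⇒ τ_on = 87.31 ns): the charge duration
programs the electrode between 0 and 3 V,
`V(t_on) = V_dd (1 − e^{−t_on/τ_on})`, and the refresh droop over a
6.326 ms pass is `1 − e^{−t_off/τ_off}` ≈ 2.5 % at the default leakage.

**Droplet array.** 2D incompressible two-phase creeping flow
(FC-3283 / water, σ = 40 mN/m, 135° contact angle, 3 mm/s injection;
Re ≈ 4·10⁻³, Ca ≈ 1·10⁻⁴) over the rasterized SDA unit array:
conservative level-set interface capture with semi-implicit surface
tension, incremental pressure projection, and an explicit
capillary-check-valve model for the 0.2 µm oil drain that is below
meniscus resolution. The simulation reproduces sequential filling,
thread severing at the plug tail, and one confined stationary droplet
per chamber.

**Synthesis orchestration.** Per-site target oligos become per-cycle,
per-base activation masks (disjoint exact covers of the unfinished
sites); each sub-step runs the addressing scheduler as a refresh over
the electrochemical hold time, and the confinement audit marks a site
deprotected only if its chamber holds a confined droplet.

See `docs/methods.md` for assumptions, parameters and numerical
choices.

## Worked example

Address the unit at (row 666, column 1111), check the refresh budget,
and time a synthesis job:

```text
$ synthchip pins --row 666 --block 44 --offset 11
row bits   : 0b001010011010
offset bits: 0b01011
enables    : [44]
units      : [UnitAddress(row=666, col=1111)]

$ synthchip scan-time --full
instances: 79075
scan time: 6.3260 ms (reported: 6.3 ms)

$ synthchip ripple
V_max = 3.0000 V, V_min = 2.9250 V, droop = 2.499 %

$ synthchip gen --kind oligos --n 16 --length 12 --seed 7 --out oligos.fa
16 oligos of length 12 -> oligos.fa
$ synthchip synthesize --fasta oligos.fa --t-hold-s 60 --out report.json
12 cycles, 192 instances, addressing 2880.000 s of 2880 s total
```

Reading: the 12-bit row code is the binary of 666; enabling block 44
with offset 11 drives column 44·25+11 = 1111. A full-array refresh
takes 79,075 instances of 80 ns (6.3 ms), so a held electrode sags by
only 2.5 % (3.000 → 2.925 V) before its next top-up. Synthesizing
16 random 12-mers needs 12 cycles x 4 base sub-steps (48 sub-steps;
192 instances, one per distinct within-block offset among each
sub-step's active sites), each holding 60 s while the refresh
scheduler loops.

The droplet simulation (several minutes):

```bash
synthchip droplets --nx 4 --ny 4 --out runs/
```

writes the per-chamber droplet-area time series (`census.csv`) and a
summary with the per-column steady means in µm².

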