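# Unified nearest-neighbor thermodynamic parameters for DNA/DNA duplexes
# (SantaLucia 1998 unified set). One Watson-Crick stack per line, read 5'->3'
# on the top strand; the bottom strand is the Watson-Crick complement.
# Columns: stack <TAB> dH (kcal/mol) <TAB> dS (cal/(mol*K))
AA	-7.9	-22.2
AC	-8.4	-22.4
AG	-7.8	-21.0
AT	-7.2	-20.4
CA	-8.5	-22.7
CC	-8.0	-19.9
CG	-10.6	-27.2
CT	-7.8	-21.0
GA	-8.2	-22.2
GC	-9.8	-24.4
GG	-8.0	-19.9
GT	-8.4	-22.4
TA	-7.2	-21.3
TC	-8.2	-22.2
TG	-8.5	-22.7
TT	-7.9	-22.2
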