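word	class
G2P	nuclear
G11P	nuclear
G8P	nuclear
P11P	nuclear
P5P	nuclear
P3Q	nuclear
P5Q	nuclear
K1K	nuclear
K6K	nuclear
K10K	nuclear
K2K	nuclear
K5K	nuclear
K0K	nuclear
K3K	nuclear
K4K	nuclear
E4E	nuclear
E1E	nuclear
E8E	nuclear
E0E	nuclear
P1T	nuclear
P0T	nuclear
P6T	nuclear
P10T	nuclear
G2G	nuclear
G1G	nuclear
G5G	nuclear
P1S	nuclear
S6P	nuclear
P3G	nuclear
G4P	nuclear
P0G	nuclear
Q11Q	nuclear
Q10Q	nuclear
Q5Q	nuclear
R13R	nuclear
R11R	nuclear
R10R	nuclear
R9R	nuclear
R12R	nuclear
R7R	nuclear
R3R	nuclear
R4R	nuclear
C8S	nuclear
S2C	nuclear
S6C	nuclear
N6P	nuclear
P12N	nuclear
S9D	nuclear
E12D	nuclear
D12D	nuclear
D4D	nuclear
D13D	nuclear
S12T	nuclear
S8T	nuclear
S10T	nuclear
K0R	nuclear
K2R	nuclear
R2R	nuclear
R0R	nuclear
R0K	nuclear
R2K	nuclear
K1R	nuclear
R1K	nuclear
R3K	nuclear
K4R	nuclear
M3P	nuclear
P12M	nuclear
R1H	nuclear
Q8R	nuclear
Q2H	nuclear
H0R	nuclear
S7Q	nuclear
Q12S	nuclear
S13H	nuclear
S10H	nuclear
S2H	nuclear
H6S	nuclear
S12H	nuclear
P7Y	nuclear
P4Y	nuclear
Y5P	nuclear
N3N	nuclear
N6N	nuclear
N0N	nuclear
K1H	nuclear
H0K	nuclear
H6K	nuclear
K10H	nuclear
D2S	nuclear
D5S	nuclear
K8S	nuclear
D0S	nuclear
N8N	nuclear
H8N	nuclear
H5N	nuclear
S6L	nuclear
T4E	nuclear
E13S	nuclear
T6E	nuclear
S13S	nuclear
S10S	nuclear
H0H	nuclear
H4H	nuclear
H1H	nuclear
H13H	nuclear
N0E	nuclear
N0K	nuclear
N4K	nuclear
K1N	nuclear
D2T	nuclear
G6L	nuclear
G8L	nuclear
E8C	nuclear
K1C	nuclear
K5C	nuclear
K7C	nuclear
C2C	nuclear
C0C	nuclear
K3C	nuclear
C4K	nuclear
H8C	nuclear
H12C	nuclear
H13C	nuclear
H10C	nuclear
D6I	nuclear
D10I	nuclear
D12I	nuclear
A13Q	nuclear
A6Q	nuclear
Q9A	nuclear
Q6A	nuclear
S11S	nuclear
M3S	nuclear
Q13T	nuclear
K9T	nuclear
Q1T	nuclear
Q9T	nuclear
N1S	nuclear
S7N	nuclear
N8S	nuclear
H1I	nuclear
I0H	nuclear
E12I	nuclear
S2E	nuclear
E11I	nuclear
D6A	nuclear
S3D	nuclear
D8A	nuclear
M13Q	nuclear
M3Q	nuclear
L13S	nuclear
L12S	nuclear
V6S	nuclear
S9N	nuclear
S13G	nuclear
E9S	nuclear
S3S	nuclear
N0S	nuclear
S3N	nuclear
H1Q	nuclear
H10Q	nuclear
H3Q	nuclear
H5Q	nuclear
T7E	nuclear
T8E	nuclear
T12E	nuclear
T9E	nuclear
W13K	nuclear
W11K	nuclear
N11I	nuclear
I12N	nuclear
M13D	nuclear
M2D	nuclear
F13D	nuclear
L1H	nuclear
H1L	nuclear
A3H	nuclear
L5H	nuclear
R0G	nuclear
A9H	nuclear
H10A	nuclear
P3R	nuclear
A10H	nuclear
L2L	non_nuclear
L2F	non_nuclear
F5L	non_nuclear
F2L	non_nuclear
M0V	non_nuclear
M1V	non_nuclear
V0M	non_nuclear
V1M	non_nuclear
V3V	non_nuclear
V2V	non_nuclear
A3V	non_nuclear
A8V	non_nuclear
A12I	non_nuclear
A6I	non_nuclear
A4I	non_nuclear
I2A	non_nuclear
E11L	non_nuclear
L11Q	non_nuclear
Q11L	non_nuclear
L11E	non_nuclear
Q5W	non_nuclear
Q13W	non_nuclear
S7W	non_nuclear
Q12W	non_nuclear
I13I	non_nuclear
I9I	non_nuclear
I12I	non_nuclear
I10I	non_nuclear
Y6Y	non_nuclear
Y0Y	non_nuclear
Y5Y	non_nuclear
Y12Y	non_nuclear
V0N	non_nuclear
L2N	non_nuclear
I2Q	non_nuclear
I2S	non_nuclear
R11A	non_nuclear
R8A	non_nuclear
R1A	non_nuclear
K1L	non_nuclear
L1K	non_nuclear
L0K	non_nuclear
F10A	non_nuclear
F11A	non_nuclear
F11S	non_nuclear
F10S	non_nuclear
L8A	non_nuclear
L4A	non_nuclear
L5A	non_nuclear
A6L	non_nuclear
F3F	non_nuclear
F4F	non_nuclear
F10F	non_nuclear
F13F	non_nuclear
L8L	non_nuclear
L3L	non_nuclear
I3L	non_nuclear
L12L	non_nuclear
V11D	non_nuclear
V13D	non_nuclear
V7D	non_nuclear
V4D	non_nuclear
I5E	non_nuclear
I4D	non_nuclear
I12E	non_nuclear
E5I	non_nuclear
W8P	non_nuclear
W9P	non_nuclear
W10P	non_nuclear
W3P	non_nuclear
V5V	non_nuclear
V13V	non_nuclear
G2V	non_nuclear
G11V	non_nuclear
S2S	non_nuclear
S4S	non_nuclear
A5S	non_nuclear
S9S	non_nuclear
W1H	non_nuclear
H10W	non_nuclear
W8H	non_nuclear
Y10W	non_nuclear
M3M	non_nuclear
M2M	non_nuclear
M13M	non_nuclear
M0M	non_nuclear
T0T	non_nuclear
T13T	non_nuclear
T7T	non_nuclear
T1T	non_nuclear
H1Y	non_nuclear
H3Y	non_nuclear
H13Y	non_nuclear
H7Y	non_nuclear
F12C	non_nuclear
F9C	non_nuclear
F0C	non_nuclear
F10C	non_nuclear
A7K	non_nuclear
A3K	non_nuclear
A10A	non_nuclear
A4A	non_nuclear
A5A	non_nuclear
A9A	non_nuclear
Y2G	non_nuclear
Y0G	non_nuclear
G0Y	non_nuclear
G0F	non_nuclear
F2K	non_nuclear
K0F	non_nuclear
K3F	non_nuclear
Q13L	non_nuclear
L13Q	non_nuclear
L1T	non_nuclear
L10Q	non_nuclear
C12I	non_nuclear
I12C	non_nuclear
C10I	non_nuclear
C3I	non_nuclear
W4E	non_nuclear
W0L	non_nuclear
W5L	non_nuclear
W1L	non_nuclear
Y7T	non_nuclear
Y7V	non_nuclear
Y6V	non_nuclear
V5Y	non_nuclear
E1M	non_nuclear
L9K	non_nuclear
R11M	non_nuclear
I10K	non_nuclear
I13K	non_nuclear
F13K	non_nuclear
T1K	non_nuclear
K5I	non_nuclear
K2V	non_nuclear
H10L	non_nuclear
L12H	non_nuclear
H8L	non_nuclear
E13L	non_nuclear
E13I	non_nuclear
E10V	non_nuclear
N13L	non_nuclear
K13N	non_nuclear
K12N	non_nuclear
I9N	non_nuclear
V10N	non_nuclear
V12N	non_nuclear
V1N	non_nuclear
R10Q	non_nuclear
D3R	non_nuclear
R2D	non_nuclear
V7G	non_nuclear
M11G	non_nuclear
V13G	non_nuclear
L3G	non_nuclear
I6N	non_nuclear
I5N	non_nuclear
V9I	non_nuclear
I11N	non_nuclear
K7L	non_nuclear
V4H	non_nuclear
H12V	non_nuclear
V8H	non_nuclear
H4V	non_nuclear
F9E	non_nuclear
D13L	non_nuclear
D12L	non_nuclear
L3D	non_nuclear
D9L	non_nuclear
H11M	non_nuclear
L10M	non_nuclear
M7H	non_nuclear
H12I	non_nuclear
E9L	non_nuclear
E11A	non_nuclear
E12A	non_nuclear
A5E	non_nuclear
E10A	non_nuclear
I4N	non_nuclear
N0I	non_nuclear
N13I	non_nuclear
N9I	non_nuclear
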