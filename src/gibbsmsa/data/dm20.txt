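# compact 20-component mixture (substitution profiles, |alpha|=2.5)
# residues in order ACDEFGHIKLMNPQRSTVWY
20
0.078050 0.755291 0.046571 0.064884 0.107687 0.046643 0.178468 0.026600 0.087963 0.098261 0.154285 0.038370 0.054276 0.089006 0.072943 0.087740 0.243600 0.141309 0.155824 0.011376 0.038902
0.019250 0.202169 1.128253 0.049123 0.040764 0.049940 0.067558 0.020138 0.094180 0.052603 0.165190 0.041082 0.041091 0.047649 0.039049 0.046971 0.130409 0.106983 0.117972 0.017225 0.041651
0.053640 0.089509 0.015610 0.984246 0.288769 0.031269 0.119644 0.035664 0.041698 0.093159 0.051716 0.018189 0.145545 0.084385 0.097801 0.058820 0.163307 0.094732 0.052232 0.007626 0.026079
0.062950 0.122958 0.010722 0.239011 0.793360 0.030373 0.082177 0.048992 0.040503 0.180979 0.071042 0.024986 0.099967 0.081967 0.189997 0.114270 0.158628 0.092018 0.071750 0.010476 0.035825
0.038560 0.107622 0.026543 0.052300 0.061377 0.850715 0.071927 0.042881 0.141804 0.056005 0.248723 0.061857 0.043749 0.035872 0.041575 0.050009 0.098176 0.080540 0.125602 0.051871 0.250852
0.073770 0.177362 0.015466 0.086191 0.071524 0.030980 1.341092 0.024985 0.029212 0.065264 0.051237 0.018021 0.101964 0.059117 0.048448 0.058276 0.161796 0.066366 0.051748 0.015112 0.025838
0.021990 0.095528 0.016660 0.092846 0.154094 0.066744 0.090290 0.861261 0.044502 0.099423 0.078055 0.027453 0.155332 0.063682 0.104377 0.125552 0.123241 0.071490 0.055744 0.016278 0.157447
0.051420 0.142700 0.035195 0.049036 0.057546 0.099702 0.047686 0.020102 0.531813 0.052509 0.466397 0.082018 0.041018 0.047564 0.038980 0.046887 0.092049 0.106792 0.471048 0.012158 0.058799
0.057440 0.129055 0.015915 0.088693 0.208174 0.031879 0.086251 0.036360 0.042511 0.759811 0.105449 0.037088 0.104923 0.086031 0.141009 0.239872 0.166493 0.096580 0.075308 0.010996 0.037601
0.090190 0.140071 0.034547 0.034034 0.056486 0.097865 0.046807 0.019732 0.261007 0.072891 0.915605 0.113854 0.040263 0.046687 0.054110 0.065087 0.090352 0.104824 0.231184 0.016878 0.057715
0.022430 0.144066 0.035532 0.049505 0.082162 0.100656 0.068083 0.028701 0.189824 0.106024 0.470860 0.331213 0.058564 0.067909 0.111306 0.094672 0.131422 0.107814 0.237778 0.024549 0.059361
0.044870 0.088528 0.015439 0.172085 0.142802 0.030927 0.167348 0.070547 0.041241 0.130303 0.072336 0.025441 0.814303 0.059015 0.096729 0.116352 0.228420 0.132503 0.051659 0.007543 0.036478
0.052030 0.124381 0.015338 0.085481 0.100318 0.021726 0.083128 0.024779 0.040972 0.091537 0.071864 0.025275 0.050562 1.326646 0.067951 0.057796 0.113465 0.093083 0.072580 0.007494 0.025625
0.042640 0.131344 0.016197 0.127656 0.299624 0.032445 0.087781 0.052333 0.043265 0.193322 0.107320 0.053380 0.106784 0.087557 0.574042 0.172623 0.169446 0.098293 0.076643 0.015826 0.054119
0.051290 0.141538 0.017454 0.068782 0.161440 0.034963 0.094595 0.056395 0.046623 0.294619 0.115650 0.040675 0.115073 0.066718 0.154649 0.744087 0.129116 0.105923 0.058402 0.012059 0.041238
0.071200 0.252508 0.031139 0.122709 0.144007 0.044106 0.168759 0.035571 0.058815 0.131402 0.103161 0.036283 0.145164 0.084164 0.097545 0.082967 0.651519 0.188968 0.073673 0.010757 0.036785
0.058410 0.183353 0.031977 0.089102 0.104568 0.045292 0.086649 0.025829 0.085415 0.095415 0.149816 0.037259 0.105408 0.086428 0.070830 0.085199 0.236544 0.776208 0.151311 0.015622 0.037775
0.064410 0.195697 0.034129 0.047551 0.078918 0.068365 0.065395 0.019494 0.364661 0.072011 0.319805 0.079535 0.039776 0.065228 0.053456 0.045467 0.089261 0.146453 0.645989 0.011790 0.057018
0.013300 0.063772 0.022243 0.030991 0.051434 0.126024 0.085241 0.025410 0.042013 0.046932 0.104215 0.036653 0.025924 0.030060 0.049271 0.041907 0.058175 0.067493 0.052627 1.390970 0.148644
0.032160 0.095616 0.023582 0.046466 0.077118 0.267221 0.063903 0.107757 0.089085 0.070368 0.156254 0.038860 0.054969 0.045071 0.073874 0.062834 0.087225 0.071556 0.111591 0.065173 0.891477
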